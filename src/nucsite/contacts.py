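"""Distance-based binding-site labelling and contact-channel decomposition.

A residue is *binding* if any of its atoms lies within a cutoff
(default 4.5 Å, inclusive) of any atom of the bound nucleotide.  Beyond
the overall label, contacts are decomposed into four channels by protein
atom group × ligand atom group:

    main chain × base, main chain × phosphate,
    side chain × base, side chain × phosphate.

Ribose-mediated contacts count toward the overall label but toward no
channel.  Hydrogen atoms are excluded from distance checks by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import LigandInstance, ProteinChain, ResidueRecord

__all__ = [
    "MAIN_CHAIN_ATOMS",
    "CHANNELS",
    "ResidueLabelSet",
    "residue_ligand_contact",
    "classify_protein_atom",
    "label_chain",
    "labels_to_tsv",
]

#: Backbone atom names; CB is side chain, the terminal carboxylate OXT is
#: main chain.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Channel keys in canonical order (protein group _ ligand group).
CHANNELS = ("mc_base", "mc_phos", "sc_base", "sc_phos")

_CHANNEL_GROUPS = {
    "mc_base": ("main_chain", "base"),
    "mc_phos": ("main_chain", "phosphate"),
    "sc_base": ("side_chain", "base"),
    "sc_phos": ("side_chain", "phosphate"),
}


@dataclass
class ResidueLabelSet:
    """Per-residue binding labels for one chain against one ligand type."""

    chain_ref: str
    ligand_het: str
    overall: np.ndarray                      # bool, length L
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.overall = np.asarray(self.overall, dtype=bool)
        for key in self.channels:
            self.channels[key] = np.asarray(self.channels[key], dtype=bool)
            if self.channels[key].shape != self.overall.shape:
                raise ValueError(f"channel {key} length mismatch")

    def __len__(self) -> int:
        return len(self.overall)

    @property
    def channel_union(self) -> np.ndarray:
        union = np.zeros_like(self.overall)
        for vec in self.channels.values():
            union |= vec
        return union

    @property
    def n_binding(self) -> int:
        return int(self.overall.sum())

    @property
    def n_nonbinding(self) -> int:
        return int((~self.overall).sum())


def classify_protein_atom(residue_type: str, atom_name: str) -> str:
    """Return ``"main_chain"`` for N/CA/C/O/OXT, ``"side_chain"`` otherwise."""
    return "main_chain" if atom_name.strip().upper() in MAIN_CHAIN_ATOMS else "side_chain"


def _residue_coords(
    residue: ResidueRecord, group: str | None, include_hydrogens: bool
) -> np.ndarray:
    sel = []
    for atom in residue.atoms:
        if not include_hydrogens and atom.element in ("H", "D"):
            continue
        if group is not None and classify_protein_atom(residue.residue_type, atom.name) != group:
            continue
        sel.append(atom.coord)
    return np.array(sel) if sel else np.empty((0, 3))


def _ligand_coords(
    ligands: list[LigandInstance], group: str | None, include_hydrogens: bool
) -> np.ndarray:
    blocks = []
    for lig in ligands:
        for atom, tag in zip(lig.atoms, lig.tags):
            if not include_hydrogens and atom.element in ("H", "D"):
                continue
            if group is not None and tag != group:
                continue
            blocks.append(atom.coord)
    return np.array(blocks) if blocks else np.empty((0, 3))


def _min_dist_ok(a: np.ndarray, b: np.ndarray, cutoff: float) -> bool:
    if a.size == 0 or b.size == 0:
        return False
    return bool(cdist(a, b).min() <= cutoff)


def residue_ligand_contact(
    residue: ResidueRecord,
    ligand: LigandInstance,
    cutoff: float = 4.5,
    include_hydrogens: bool = False,
) -> bool:
    """True iff the minimum atom–atom distance is ≤ ``cutoff`` (inclusive)."""
    if not residue.atoms or not ligand.atoms:
        raise ValueError("residue and ligand atom lists must be non-empty")
    return _min_dist_ok(
        _residue_coords(residue, None, include_hydrogens),
        _ligand_coords([ligand], None, include_hydrogens),
        cutoff,
    )


def label_chain(
    chain: ProteinChain,
    ligands: list[LigandInstance],
    cutoff: float = 4.5,
    include_hydrogens: bool = False,
) -> ResidueLabelSet:
    """Label every residue of ``chain`` against all copies of one ligand type.

    A residue is binding if it contacts *any* copy of the ligand.  Channel
    labels require a contact between the named protein group and the named
    ligand group; ribose contacts set only the overall label.
    """
    if not ligands:
        raise ValueError("label_chain needs at least one ligand instance")
    het_codes = {lig.het_code for lig in ligands}
    if len(het_codes) != 1:
        raise ValueError(f"ligands must share one het code, got {sorted(het_codes)}")

    groups: dict[tuple[str | None, str | None], np.ndarray] = {}
    lig_all = _ligand_coords(ligands, None, include_hydrogens)
    lig_by_group = {
        g: _ligand_coords(ligands, g, include_hydrogens)
        for g in ("base", "phosphate")
    }

    n = len(chain.residues)
    overall = np.zeros(n, dtype=bool)
    channels = {key: np.zeros(n, dtype=bool) for key in CHANNELS}
    for i, residue in enumerate(chain.residues):
        res_all = _residue_coords(residue, None, include_hydrogens)
        overall[i] = _min_dist_ok(res_all, lig_all, cutoff)
        if not overall[i]:
            continue  # channels are subsets of the overall contact set
        for key, (pgroup, lgroup) in _CHANNEL_GROUPS.items():
            channels[key][i] = _min_dist_ok(
                _residue_coords(residue, pgroup, include_hydrogens),
                lig_by_group[lgroup],
                cutoff,
            )
    return ResidueLabelSet(chain.ref, het_codes.pop(), overall, channels)


def labels_to_tsv(chain: ProteinChain, labels: ResidueLabelSet) -> str:
    """Label vectors as TSV rows (one per residue), with header."""
    header = "structure_id\tchain_id\tseq_index\tresidue_type\tligand_het\toverall\t" + "\t".join(CHANNELS)
    lines = [header]
    for i, res in enumerate(chain.residues):
        flags = [str(int(labels.overall[i]))] + [
            str(int(labels.channels[c][i])) for c in CHANNELS
        ]
        lines.append(
            f"{chain.structure_id}\t{chain.chain_id}\t{i}\t{res.residue_type}\t"
            f"{labels.ligand_het}\t" + "\t".join(flags)
        )
    return "\n".join(lines) + "\n"
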