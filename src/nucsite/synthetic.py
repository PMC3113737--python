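"""Synthetic complexes and profiles with controllable binding signal.

The generator builds toy protein–nucleotide complexes as PDB text and
matching sequence profiles so that every stage of the pipeline — parsing,
contact labelling, propensity statistics, feature encoding and model
fitting — can be exercised without downloading real structures.

Geometry.  The chain backbone follows an idealised helix (2.3 Å radius,
1.5 Å rise, 100° twist per residue).  The ligand, an idealised template
with the correct atom names for its het code, is translated to a point
well clear of the chain; every residue requested as *binding* then
reaches it with a pseudo side-chain atom placed 3.5 Å from the nearest
ligand atom, while all other residues stay ≥ 6 Å away.  The margins
(≤ 4.0 Å for binding, ≥ 6.0 Å for non-binding) straddle the 4.5 Å
labelling cutoff with a buffer, so placement round-off cannot flip a
label.  The generator validates its own geometry and, in
:func:`make_ligand_dataset`, re-derives the labels through the contacts
module — the geometric path, not the requested positions, is the ground
truth.

Profiles.  Background scores are Normal(0, noise_sd); rows of binding
residues additionally get ``signal_shift`` added on ``signal_dims``.
All randomness is seed-deterministic per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA1_TO_3, AA_ORDER
from .contacts import ResidueLabelSet, label_chain
from .features import SequenceProfile
from .model import DatasetEntry, LigandDataset
from .structure_io import (
    AtomRecord,
    LIGAND_CLASSES,
    LigandInstance,
    ProteinChain,
    ResidueRecord,
    classify_ligand_atoms,
    parse_complex,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "make_toy_complex",
    "make_toy_profile",
    "make_ligand_dataset",
    "write_fixture_dir",
    "write_psiblast_ascii",
]


class FixtureError(ValueError):
    """Raised when a fixture spec is unsatisfiable or self-checks fail."""


# helix geometry (Å / degrees)
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0
_LIGAND_RADIAL_OFFSET = 30.0
_CONTACT_DIST = 3.5      # planted side-chain atom to nearest ligand atom
_MAX_BINDING_DIST = 4.0  # construction guarantee for binding residues
_MIN_NONBINDING_DIST = 6.0


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic ligand dataset.

    Defaults are the planted-signal conditions used throughout the test
    and acceptance fixtures: 40 proteins of 60 residues with 6 binding
    residues each, a +6 shift on 3 profile dimensions over unit noise.
    """

    n_proteins: int = 40
    chain_length: int = 60
    ligand_het: str = "ATP"
    n_binding: int = 6
    binding_positions: tuple[tuple[int, ...], ...] | None = None
    signal_dims: tuple[int, ...] = (0, 1, 2)
    signal_shift: float = 6.0
    noise_sd: float = 1.0
    decoy_dims: tuple[int, ...] = ()
    n_decoys: int | None = None
    seed: int = 0
    resolution: float = 1.5

    def __post_init__(self) -> None:
        if self.ligand_het not in LIGAND_CLASSES:
            raise FixtureError(f"unsupported ligand het code {self.ligand_het!r}")
        if self.n_binding > self.chain_length:
            raise FixtureError(
                f"{self.n_binding} binding positions do not fit in a "
                f"{self.chain_length}-residue chain"
            )
        if not all(0 <= d < 20 for d in self.signal_dims):
            raise FixtureError("signal_dims must be profile column indices in [0, 20)")
        if not all(0 <= d < 20 for d in self.decoy_dims):
            raise FixtureError("decoy_dims must be profile column indices in [0, 20)")
        if self.binding_positions is not None:
            for i, positions in enumerate(self.binding_positions):
                if not all(0 <= p < self.chain_length for p in positions):
                    raise FixtureError(f"protein {i}: binding positions out of range")

    def positions_for(self, protein_index: int) -> list[int]:
        """Binding positions for one protein (explicit, or seeded draw)."""
        if self.binding_positions is not None:
            return sorted(set(self.binding_positions[protein_index]))
        rng = np.random.default_rng(
            np.random.SeedSequence((self.seed, protein_index, 0))
        )
        return sorted(
            rng.choice(self.chain_length, size=self.n_binding, replace=False).tolist()
        )

    def structure_id(self, protein_index: int) -> str:
        return f"T{protein_index:03d}"


# ---------------------------------------------------------------------------
# Idealised ligand templates

def _ring(names: list[str], radius: float, center: np.ndarray) -> list[tuple[str, np.ndarray]]:
    out = []
    for k, name in enumerate(names):
        angle = 2.0 * np.pi * k / len(names)
        out.append((name, center + radius * np.array([np.cos(angle), np.sin(angle), 0.0])))
    return out


def _ligand_template(het_code: str) -> list[tuple[str, np.ndarray]]:
    """Idealised atoms (correct names, schematic geometry) for one het code."""
    base, n_phos, cyclic = LIGAND_CLASSES[het_code]
    if base == "adenine":
        base_names = ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"]
    else:
        base_names = ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N2", "N1", "C6", "O6"]
    atoms = _ring(base_names, 1.4, np.zeros(3))
    ribose_names = ["C1'", "C2'", "C3'", "C4'", "O4'", "C5'", "O2'", "O3'", "O5'"]
    atoms += _ring(ribose_names, 1.2, np.array([3.6, 0.0, 0.0]))
    if n_phos == 1:
        p_names = [["P", "O1P", "O2P"] + ([] if cyclic else ["O3P"])]
    elif n_phos == 2:
        p_names = [["PA", "O1A", "O2A", "O3A"], ["PB", "O1B", "O2B", "O3B"]]
    else:
        p_names = [["PA", "O1A", "O2A", "O3A"], ["PB", "O1B", "O2B", "O3B"],
                   ["PG", "O1G", "O2G", "O3G"]]
    for k, group in enumerate(p_names):
        center = np.array([6.5 + 2.6 * k, 0.0, 0.0])
        atoms.append((group[0], center))
        for j, oxy in enumerate(group[1:]):
            angle = 2.0 * np.pi * j / max(len(group) - 1, 1)
            atoms.append(
                (oxy, center + 1.5 * np.array([0.0, np.cos(angle), np.sin(angle)]))
            )
    centroid = np.mean([c for _, c in atoms], axis=0)
    return [(name, coord - centroid) for name, coord in atoms]


def _element_of(atom_name: str) -> str:
    return atom_name.strip("0123456789'")[:1]


def _backbone_residue(aa: str, index: int) -> ResidueRecord:
    """Residue on the idealised helix with N/CA/C/O (+CB) near the axis."""
    angle = np.deg2rad(_HELIX_TWIST_DEG * index)
    radial = np.array([np.cos(angle), np.sin(angle), 0.0])
    tangent = np.array([-np.sin(angle), np.cos(angle), 0.0])
    ca = _HELIX_RADIUS * radial + np.array([0.0, 0.0, _HELIX_RISE * index])
    atoms = [
        AtomRecord("N", "N", ca - 1.2 * tangent + np.array([0, 0, -0.5])),
        AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", ca + 1.2 * tangent + np.array([0, 0, 0.5])),
        AtomRecord("O", "O", ca + 1.2 * tangent + np.array([0, 0, 1.7])),
    ]
    if aa != "G":
        atoms.append(AtomRecord("CB", "C", ca + 1.5 * radial))
    return ResidueRecord(aa, AA1_TO_3.get(aa, "UNK"), index, atoms)


def _build_complex(
    spec: FixtureSpec, protein_index: int
) -> tuple[ProteinChain, LigandInstance]:
    positions = spec.positions_for(protein_index)
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, protein_index, 1))
    )
    sequence = rng.choice(list(AA_ORDER), size=spec.chain_length)
    residues = [_backbone_residue(aa, i) for i, aa in enumerate(sequence)]

    z_anchor = _HELIX_RISE * (
        float(np.mean(positions)) if positions else spec.chain_length / 2.0
    )
    shift = np.array([_LIGAND_RADIAL_OFFSET, 0.0, z_anchor])
    template = _ligand_template(spec.ligand_het)
    lig_atoms = [
        AtomRecord(name, _element_of(name), coord + shift) for name, coord in template
    ]
    lig_coords = np.array([a.coord for a in lig_atoms])

    for pos in positions:
        ca = residues[pos].atoms[1].coord
        nearest = lig_coords[np.argmin(np.linalg.norm(lig_coords - ca, axis=1))]
        direction = (ca - nearest) / np.linalg.norm(ca - nearest)
        planted = nearest + _CONTACT_DIST * direction
        residues[pos].atoms.append(AtomRecord("CG", "C", planted))

    # geometric self-check: margins straddle the 4.5 Å labelling cutoff
    binding = set(positions)
    for res in residues:
        dmin = np.min(
            np.linalg.norm(
                lig_coords[None, :, :] - res.coords()[:, None, :], axis=2
            )
        )
        if res.seq_index in binding and dmin > _MAX_BINDING_DIST:
            raise FixtureError(
                f"protein {protein_index}: residue {res.seq_index} placed "
                f"{dmin:.2f} Å from ligand, expected <= {_MAX_BINDING_DIST}"
            )
        if res.seq_index not in binding and dmin < _MIN_NONBINDING_DIST:
            raise FixtureError(
                f"protein {protein_index}: non-binding residue {res.seq_index} "
                f"only {dmin:.2f} Å from ligand"
            )

    chain = ProteinChain(
        spec.structure_id(protein_index), "A", residues, spec.resolution
    )
    base, n_phos, cyclic = LIGAND_CLASSES[spec.ligand_het]
    tags = classify_ligand_atoms(spec.ligand_het, [a.name for a in lig_atoms])
    ligand = LigandInstance(spec.ligand_het, base, n_phos, cyclic, lig_atoms, tags)
    return chain, ligand


def make_toy_complex(spec: FixtureSpec, protein_index: int) -> str:
    """PDB text for one toy complex; byte-identical for identical inputs."""
    chain, ligand = _build_complex(spec, protein_index)
    return write_pdb([chain], [ligand], structure_id=chain.structure_id)


def make_toy_profile(
    spec: FixtureSpec, labels: ResidueLabelSet, protein_index: int = 0
) -> SequenceProfile:
    """Noise profile with ``signal_shift`` planted on binding residues' rows.

    If ``decoy_dims`` is non-empty, the same shift is additionally planted
    on ``n_decoys`` randomly chosen *non-binding* rows on those dims.
    Decoys carry no label information; they equalise the marginal feature
    distribution between two datasets whose informative dims are swapped,
    so that cross-prediction between them measures signal transfer rather
    than mere novelty of large profile values.
    """
    if len(labels) != spec.chain_length:
        raise FixtureError(
            f"labels length {len(labels)} != chain length {spec.chain_length}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, protein_index, 2))
    )
    matrix = rng.normal(0.0, spec.noise_sd, size=(spec.chain_length, 20))
    rows = np.flatnonzero(labels.overall)
    if rows.size and spec.signal_dims:
        matrix[np.ix_(rows, list(spec.signal_dims))] += spec.signal_shift
    if spec.decoy_dims:
        n_decoys = spec.n_decoys if spec.n_decoys is not None else len(rows)
        nonbinding = np.flatnonzero(~labels.overall)
        decoys = rng.choice(nonbinding, size=min(n_decoys, nonbinding.size),
                            replace=False)
        if decoys.size:
            matrix[np.ix_(sorted(decoys), list(spec.decoy_dims))] += spec.signal_shift
    return SequenceProfile(labels.chain_ref, matrix, source="synthetic")


def make_ligand_dataset(spec: FixtureSpec, cutoff: float = 4.5) -> LigandDataset:
    """Assemble a full dataset, deriving labels geometrically.

    Every complex is serialised to PDB text, re-parsed, and labelled by
    the contacts module; the recovered labels must equal the requested
    binding positions or a :class:`FixtureError` is raised.
    """
    entries = []
    for i in range(spec.n_proteins):
        pdb_text = make_toy_complex(spec, i)
        chains, ligands = parse_complex(pdb_text)
        if len(chains) != 1 or not ligands:
            raise FixtureError(f"protein {i}: round-trip lost chain or ligand")
        labels = label_chain(chains[0], ligands, cutoff=cutoff)
        recovered = set(np.flatnonzero(labels.overall).tolist())
        requested = set(spec.positions_for(i))
        if recovered != requested:
            raise FixtureError(
                f"protein {i}: geometric labels {sorted(recovered)} != "
                f"requested positions {sorted(requested)}"
            )
        profile = make_toy_profile(spec, labels, i)
        entries.append(DatasetEntry(chains[0], profile, labels))
    return LigandDataset(spec.ligand_het, entries)


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write PDB files, profile TSVs and a manifest for one fixture set."""
    from .features import profile_to_tsv
    from .structure_io import write_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = make_ligand_dataset(spec)
    chains = []
    for i, entry in enumerate(dataset.entries):
        (out / f"{entry.chain.ref}.pdb").write_text(make_toy_complex(spec, i))
        (out / f"{entry.chain.ref}.profile.tsv").write_text(
            profile_to_tsv(entry.profile)
        )
        chains.append(entry.chain)
    (out / "manifest.tsv").write_text(write_manifest(chains))
    return out


def write_psiblast_ascii(profile: SequenceProfile, sequence: str) -> str:
    """Render a profile in PSI-BLAST ``-out_ascii_pssm`` layout.

    Used to build parser fixtures; scores are rounded to integers as in
    real PSSM files, and the percentage/information columns are padded
    with zeros.
    """
    if len(sequence) != len(profile):
        raise ValueError("sequence and profile lengths differ")
    header = (
        "\nLast position-specific scoring matrix computed, weighted, and scaled\n"
        "           " + "   ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER) + "\n"
    )
    lines = [header.rstrip("\n")]
    for i, row in enumerate(profile.matrix):
        scores = " ".join(f"{int(round(v)):3d}" for v in row)
        percents = " ".join("  0" for _ in range(20))
        lines.append(f"{i + 1:5d} {sequence[i]}  {scores} {percents}  0.00 0.00")
    lines.append("\n                      K         Lambda\n")
    return "\n".join(lines) + "\n"
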