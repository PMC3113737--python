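"""Reading, curating and writing protein–nucleotide complex structures.

This module turns PDB-format text into lightweight domain objects
(:class:`ProteinChain`, :class:`LigandInstance`), applies the dataset
curation rules used throughout the package (resolution cutoff, minimum
chain length, sequence-redundancy removal) and serialises curated sets
back to PDB / FASTA / manifest form.

Heavy lifting of the PDB grammar is delegated to :mod:`gemmi`; pairwise
global alignment for redundancy removal is delegated to
:mod:`Bio.Align`.  The curation policy itself lives here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import Align

from .alphabet import AA1_TO_3, AA_ORDER, UNKNOWN

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ProteinChain",
    "LigandInstance",
    "PDBParseError",
    "LIGAND_CLASSES",
    "parse_complex",
    "classify_ligand_atoms",
    "apply_structure_filters",
    "remove_redundancy",
    "sequence_identity",
    "write_pdb",
    "write_manifest",
    "write_fasta",
]


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


#: het code -> (base, number of phosphates, cyclic?)
#: The eight adenine/guanine phosphates handled by the package.
LIGAND_CLASSES: dict[str, tuple[str, int, bool]] = {
    "CMP": ("adenine", 1, True),   # cyclic AMP
    "PCG": ("guanine", 1, True),   # cyclic GMP
    "AMP": ("adenine", 1, False),
    "ADP": ("adenine", 2, False),
    "ATP": ("adenine", 3, False),
    "5GP": ("guanine", 1, False),  # GMP
    "GDP": ("guanine", 2, False),
    "GTP": ("guanine", 3, False),
}

ADENINE_BASE_ATOMS = {"N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"}
GUANINE_BASE_ATOMS = {"N9", "C8", "N7", "C5", "C4", "N3", "C2", "N2", "N1", "C6", "O6"}

_BASE_ATOMS = {"adenine": ADENINE_BASE_ATOMS, "guanine": GUANINE_BASE_ATOMS}

# Phosphorus atoms and their directly bonded oxygens, covering both the
# lettered (O1A..O3G) and numbered (O1P..O3P / OP1..OP3) naming styles.
_PHOSPHATE_RE = re.compile(r"^(P[ABG]?|O[123][PABG]|OP[123])$")
# Ribose carbons and hydroxyl/ring oxygens (primed names; '*' normalised to "'").
_RIBOSE_RE = re.compile(r"^[CO][1-5]'$")


@dataclass
class AtomRecord:
    """One atom with PDB-convention name, element and coordinates in Å."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class ResidueRecord:
    """One amino-acid residue: type, 0-based chain position and atoms."""

    residue_type: str          # one-letter code, 'X' for UNKNOWN
    name3: str                 # original three-letter name (kept for output)
    seq_index: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def coords(self, include_hydrogens: bool = False) -> np.ndarray:
        atoms = self.atoms if include_hydrogens else [
            a for a in self.atoms if a.element not in ("H", "D")
        ]
        if not atoms:
            atoms = self.atoms
        return np.array([a.coord for a in atoms])


@dataclass
class ProteinChain:
    """A polypeptide chain extracted from one structure."""

    structure_id: str
    chain_id: str
    residues: list[ResidueRecord]
    resolution: float | None = None  # Å; None for NMR structures

    @property
    def sequence(self) -> str:
        return "".join(r.residue_type for r in self.residues)

    @property
    def ref(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LigandInstance:
    """One bound nucleotide HETATM group with base/phosphate/ribose tags."""

    het_code: str
    base: str
    n_phosphates: int
    cyclic: bool
    atoms: list[AtomRecord]
    tags: list[str]  # parallel to atoms; each "base"|"phosphate"|"ribose"

    def coords(self, group: str | None = None) -> np.ndarray:
        """Coordinates of all atoms, or only those tagged ``group``."""
        if group is None:
            sel = self.atoms
        else:
            sel = [a for a, t in zip(self.atoms, self.tags) if t == group]
        return np.array([a.coord for a in sel]) if sel else np.empty((0, 3))


def classify_ligand_atoms(het_code: str, atom_names: list[str]) -> list[str]:
    """Tag nucleotide atoms as ``base``, ``phosphate`` or ``ribose``.

    Purine-ring atoms and exocyclic substituents go to *base*, phosphorus
    atoms with their bonded non-ester oxygens to *phosphate*, sugar atoms
    (including the phosphoester O3'/O5') to *ribose*.  Unrecognised names
    fall back to *ribose* with a logged warning, never an error.
    """
    if het_code not in LIGAND_CLASSES:
        raise ValueError(f"unsupported ligand het code {het_code!r}")
    base, _, _ = LIGAND_CLASSES[het_code]
    base_atoms = _BASE_ATOMS[base]
    tags = []
    for raw in atom_names:
        name = raw.strip().replace("*", "'").upper()
        if name in base_atoms:
            tags.append("base")
        elif _PHOSPHATE_RE.match(name):
            tags.append("phosphate")
        elif _RIBOSE_RE.match(name):
            tags.append("ribose")
        else:
            logger.warning("unrecognised %s atom name %r tagged as ribose", het_code, raw)
            tags.append("ribose")
    return tags


# ---------------------------------------------------------------------------
# Parsing

_COORD_COLS = [(30, 38), (38, 46), (46, 54)]


def _precheck_coordinates(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            for lo, hi in _COORD_COLS:
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field on line {lineno}: {line.rstrip()!r}"
                    ) from None


def _header_id(text: str) -> str:
    for line in text.splitlines():
        if line.startswith("HEADER"):
            code = line[62:66].strip()
            if code:
                return code
        if line.startswith(("ATOM", "HETATM")):
            break
    return "UNKN"


def _select_altlocs(res: gemmi.Residue) -> list:
    """Keep one copy of each atom name: highest occupancy, ties → lowest altloc."""
    by_name: dict[str, list] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    picked = []
    for name in by_name:
        cands = by_name[name]
        cands.sort(key=lambda a: (-a.occ, a.altloc.replace("\x00", "")))
        picked.append(cands[0])
    return picked


def _atom_record(atom) -> AtomRecord:
    alt = atom.altloc.replace("\x00", "")
    return AtomRecord(
        name=atom.name,
        element=atom.element.name,
        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        occupancy=min(max(atom.occ, 0.0), 1.0),
        altloc=alt,
    )


def parse_complex(pdb_text: str) -> tuple[list[ProteinChain], list[LigandInstance]]:
    """Parse PDB text into protein chains and supported nucleotide ligands.

    Only the first model of multi-model (NMR) files is used; for alternate
    locations the highest-occupancy conformer of each atom is kept (ties
    broken by lowest altloc character).  HETATM groups whose het code is
    not one of the eight supported nucleotides are silently ignored.
    """
    _precheck_coordinates(pdb_text)
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise PDBParseError(f"unreadable PDB text: {exc}") from exc
    if len(structure) == 0:
        return [], []

    structure_id = _header_id(pdb_text)
    resolution = structure.resolution if structure.resolution > 0 else None
    model = structure[0]  # first model only

    chains: list[ProteinChain] = []
    ligands: list[LigandInstance] = []
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            atoms = [_atom_record(a) for a in _select_altlocs(res)]
            if res.name in LIGAND_CLASSES:
                base, n_phos, cyclic = LIGAND_CLASSES[res.name]
                tags = classify_ligand_atoms(res.name, [a.name for a in atoms])
                ligands.append(
                    LigandInstance(res.name, base, n_phos, cyclic, atoms, tags)
                )
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid() or info.is_water():
                continue  # other hetero groups, solvent, nucleic acids
            one = info.one_letter_code.upper()
            if one not in AA_ORDER:
                one = UNKNOWN
            residues.append(
                ResidueRecord(one, res.name, seq_index=len(residues), atoms=atoms)
            )
        if residues:
            chains.append(ProteinChain(structure_id, chain.name, residues, resolution))
    return chains, ligands


# ---------------------------------------------------------------------------
# Curation filters

def apply_structure_filters(
    chains: list[ProteinChain],
    max_resolution: float = 2.5,
    min_length: int = 30,
) -> list[ProteinChain]:
    """Drop chains worse than ``max_resolution`` Å or shorter than ``min_length``.

    A resolution value *numerically greater* than the cutoff means a worse
    (lower) resolution and is discarded; chains without a resolution value
    (NMR structures) pass the resolution filter.
    """
    kept = []
    for chain in chains:
        if chain.resolution is not None and chain.resolution > max_resolution:
            continue
        if len(chain) < min_length:
            continue
        kept.append(chain)
    return kept


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    # match +1, mismatch 0, linear gap -1 (global); the simplest reproducible
    # scoring for identity-based redundancy removal
    global _aligner
    if _aligner is None:
        _aligner = Align.PairwiseAligner()
        _aligner.mode = "global"
        _aligner.match_score = 1.0
        _aligner.mismatch_score = 0.0
        _aligner.open_gap_score = -1.0
        _aligner.extend_gap_score = -1.0
    return _aligner


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: identical positions / length of shorter sequence."""
    if not a or not b:
        return 0.0
    alignment = _get_aligner().align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def remove_redundancy(
    chains: list[ProteinChain], identity_cutoff: float = 0.30
) -> list[ProteinChain]:
    """Greedy redundancy removal at a pairwise sequence-identity cutoff.

    Chains are visited in order of decreasing length (ties by structure id
    then chain id); a chain is kept only if its identity to every
    already-kept chain is ≤ ``identity_cutoff``.
    """
    if not chains:
        raise ValueError("remove_redundancy requires at least one chain")
    order = sorted(
        chains, key=lambda c: (-len(c), c.structure_id, c.chain_id)
    )
    kept: list[ProteinChain] = []
    for chain in order:
        if all(
            sequence_identity(chain.sequence, other.sequence) <= identity_cutoff
            for other in kept
        ):
            kept.append(chain)
    return kept


# ---------------------------------------------------------------------------
# Serialisation

def _format_atom_line(
    record: str,
    serial: int,
    atom: AtomRecord,
    res_name: str,
    chain_id: str,
    res_seq: int,
) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    x, y, z = atom.coord
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{atom.altloc or ' ':1s}"
        f"{res_name:>3s} {chain_id:1s}{res_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(
    chains: list[ProteinChain],
    ligands: list[LigandInstance] | None = None,
    structure_id: str | None = None,
) -> str:
    """Serialise chains and ligands back to PDB text (round-trips with parse)."""
    ligands = ligands or []
    sid = (structure_id or (chains[0].structure_id if chains else "UNKN"))[:4].upper()
    lines = [f"HEADER    PROTEIN-NUCLEOTIDE COMPLEX              01-JAN-00   {sid:>4s}"]
    resolution = next((c.resolution for c in chains if c.resolution is not None), None)
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {resolution:7.2f} ANGSTROMS.")
    serial = 1
    for chain in chains:
        for res in chain.residues:
            name3 = res.name3 or AA1_TO_3.get(res.residue_type, "UNK")
            for atom in res.atoms:
                lines.append(
                    _format_atom_line("ATOM", serial, atom, name3,
                                      chain.chain_id, res.seq_index + 1)
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lig_chain = chains[0].chain_id if chains else "L"
    for i, lig in enumerate(ligands):
        for atom in lig.atoms:
            lines.append(
                _format_atom_line("HETATM", serial, atom, lig.het_code,
                                  lig_chain, 900 + i)
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_manifest(chains: list[ProteinChain]) -> str:
    """Curated chain list as TSV: structure_id, chain_id, length, resolution."""
    lines = ["structure_id\tchain_id\tlength\tresolution"]
    for c in chains:
        res = "" if c.resolution is None else f"{c.resolution:.2f}"
        lines.append(f"{c.structure_id}\t{c.chain_id}\t{len(c)}\t{res}")
    return "\n".join(lines) + "\n"


def write_fasta(chains: list[ProteinChain], width: int = 60) -> str:
    """Chain sequences as FASTA keyed by ``structure_id_chain``."""
    parts = []
    for c in chains:
        parts.append(f">{c.ref}")
        seq = c.sequence
        parts.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(parts) + "\n"
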