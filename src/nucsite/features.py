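"""PSSM sliding-window feature encoding and profile input.

Each residue is encoded from a five-residue window of its chain's
position-specific scoring matrix (PSSM): for every window slot the 20
substitution scores of that row plus a 21st *terminal* dimension, giving
a 21 × 5 = 105-dimensional vector.  Window slots that fall beyond either
chain terminus contribute zeros in the 20 score dimensions and 1 in the
terminal dimension; inside the chain the terminal dimension is 0.

Profiles come either from the synthetic generator or from PSI-BLAST
ASCII PSSM files (three search cycles against a large sequence database
is the convention for real data; an adapter for running the external
``psiblast`` executable is provided but is never required — profiles can
always be supplied as files or arrays).

Raw PSSM scores are used as-is by default.  An optional logistic
rescaling ``1/(1+exp(-x/10))`` is available for users who prefer bounded
inputs; it is off by default and every model records which mode
produced its features.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER

__all__ = [
    "SequenceProfile",
    "PSSMFormatError",
    "PsiBlastUnavailableError",
    "encode_window",
    "encode_chain",
    "logistic_scale",
    "load_psiblast_pssm",
    "build_psiblast_command",
    "run_psiblast_adapter",
    "profile_to_tsv",
    "profile_from_tsv",
]

WINDOW_HALF_WIDTH = 2
SLOT_DIM = 21           # 20 PSSM scores + 1 terminal flag
N_FEATURES = SLOT_DIM * (2 * WINDOW_HALF_WIDTH + 1)  # 105


class PSSMFormatError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed."""


class PsiBlastUnavailableError(RuntimeError):
    """Raised when the external psiblast executable is not on PATH."""


@dataclass
class SequenceProfile:
    """L×20 profile matrix for one chain, columns in canonical order."""

    chain_ref: str
    matrix: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"profile must be L x 20, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("profile contains non-finite values")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def logistic_scale(matrix: np.ndarray) -> np.ndarray:
    """Optional bounded rescaling of raw PSSM scores: 1/(1+e^(-x/10))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(matrix, dtype=float) / 10.0))


def encode_window(
    profile: SequenceProfile,
    position: int,
    half_width: int = WINDOW_HALF_WIDTH,
) -> np.ndarray:
    """Encode the residue at ``position`` as a (2·half_width+1)×21 vector."""
    length = len(profile)
    if not 0 <= position < length:
        raise IndexError(f"position {position} outside chain of length {length}")
    slots = []
    for offset in range(-half_width, half_width + 1):
        q = position + offset
        slot = np.zeros(SLOT_DIM)
        if 0 <= q < length:
            slot[:20] = profile.matrix[q]
        else:
            slot[20] = 1.0  # beyond a terminus
        slots.append(slot)
    return np.concatenate(slots)


def encode_chain(
    profile: SequenceProfile, half_width: int = WINDOW_HALF_WIDTH
) -> np.ndarray:
    """Feature matrix for the whole chain: one 105-vector per residue."""
    return np.stack(
        [encode_window(profile, i, half_width) for i in range(len(profile))]
    )


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM input

def _is_header(tokens: list[str]) -> bool:
    return len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20])


def load_psiblast_pssm(
    text: str, sequence: str | None = None, chain_ref: str = ""
) -> SequenceProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a profile.

    The first 20 score columns are read in the file's own column order
    and re-ordered to the canonical alphabet.  Header and footer noise
    lines are skipped.  If ``sequence`` is given, row count and residue
    letters are cross-checked (positions the chain reports as X are
    exempt from the letter check).
    """
    col_order: list[str] | None = None
    rows: list[list[float]] = []
    letters: list[str] = []
    for line in text.splitlines():
        tokens = line.split()
        if not tokens:
            continue
        if col_order is None:
            if _is_header(tokens):
                col_order = [t.upper() for t in tokens[:20]]
            continue
        if (
            tokens[0].isdigit()
            and len(tokens) >= 22
            and len(tokens[1]) == 1
            and tokens[1].isalpha()
        ):
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError:
                continue
            rows.append(scores)
            letters.append(tokens[1].upper())
    if col_order is None or not rows:
        raise PSSMFormatError("no PSSM header/score rows found")
    if sorted(col_order) != sorted(AA_ORDER):
        raise PSSMFormatError(f"unexpected PSSM column alphabet {col_order}")
    matrix = np.array(rows)
    perm = [col_order.index(aa) for aa in AA_ORDER]
    matrix = matrix[:, perm]
    if sequence is not None:
        if len(sequence) != len(rows):
            raise PSSMFormatError(
                f"PSSM has {len(rows)} rows but chain has {len(sequence)} residues"
            )
        for i, (file_aa, chain_aa) in enumerate(zip(letters, sequence)):
            if chain_aa != "X" and file_aa != chain_aa:
                raise PSSMFormatError(
                    f"PSSM row {i + 1} is {file_aa} but chain residue is {chain_aa}"
                )
    return SequenceProfile(chain_ref=chain_ref, matrix=matrix, source="psiblast")


# ---------------------------------------------------------------------------
# External PSI-BLAST adapter (optional; never needed for synthetic profiles)

def build_psiblast_command(
    query_fasta: str | Path,
    db_path: str | Path,
    pssm_out: str | Path,
    cycles: int = 3,
    executable: str = "psiblast",
) -> list[str]:
    """Command line for an iterative profile search that saves the PSSM."""
    return [
        executable,
        "-query", str(query_fasta),
        "-db", str(db_path),
        "-num_iterations", str(cycles),
        "-out_ascii_pssm", str(pssm_out),
        "-save_pssm_after_last_round",
    ]


def run_psiblast_adapter(
    sequence: str,
    db_path: str | Path,
    cycles: int = 3,
    chain_ref: str = "query",
    executable: str = "psiblast",
    runner=None,
) -> SequenceProfile:
    """Run PSI-BLAST for one sequence and parse the resulting ASCII PSSM.

    ``runner(command)`` may be injected for testing or alternative
    providers; the default invokes the external executable and raises a
    structured :class:`PsiBlastUnavailableError` when it is missing.
    """
    if runner is None and shutil.which(executable) is None:
        raise PsiBlastUnavailableError(
            f"{executable!r} not found on PATH; supply profiles as files or "
            "use the synthetic profile generator"
        )
    with tempfile.TemporaryDirectory(prefix="nucsite_psiblast_") as tmp:
        query = Path(tmp) / "query.fasta"
        pssm_out = Path(tmp) / "query.pssm"
        query.write_text(f">{chain_ref}\n{sequence}\n")
        command = build_psiblast_command(query, db_path, pssm_out, cycles, executable)
        if runner is None:
            subprocess.run(command, check=True, capture_output=True)
        else:
            runner(command)
        if not pssm_out.exists():
            raise PsiBlastUnavailableError("psiblast produced no ASCII PSSM output")
        return load_psiblast_pssm(pssm_out.read_text(), sequence=sequence,
                                  chain_ref=chain_ref)


# ---------------------------------------------------------------------------
# Plain-text profile container

def profile_to_tsv(profile: SequenceProfile) -> str:
    header = "pos\t" + "\t".join(AA_ORDER)
    lines = [f"# chain_ref={profile.chain_ref}\tsource={profile.source}", header]
    for i, row in enumerate(profile.matrix):
        lines.append(str(i) + "\t" + "\t".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"


def profile_from_tsv(text: str) -> SequenceProfile:
    chain_ref, source = "", "synthetic"
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            for part in line[1:].split():
                if part.startswith("chain_ref="):
                    chain_ref = part.split("=", 1)[1]
                elif part.startswith("source="):
                    source = part.split("=", 1)[1]
            continue
        if line.startswith("pos") or not line.strip():
            continue
        fields = line.split("\t")
        rows.append([float(v) for v in fields[1:21]])
    return SequenceProfile(chain_ref=chain_ref, matrix=np.array(rows), source=source)
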