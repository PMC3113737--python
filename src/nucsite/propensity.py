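"""Per-amino-acid binding propensities with bootstrap error bars.

The propensity of amino acid *i* for a ligand category is the ratio of
the relative number of binding residues of that type to the overall
relative number of binding residues, pooled over all proteins of the
category:

    P(i) = (N_b(i) / N(i)) / (N_b(all) / N(all))

P(i) > 1 means enrichment of residue type *i* at binding sites,
P(i) < 1 depletion.  Error bars come from bootstrap resampling of whole
proteins with replacement (default 500 pseudo-copies of the dataset);
the standard deviation of the propensity across pseudo-copies is the
error bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alphabet import AA_INDEX, AA_ORDER
from .contacts import CHANNELS, ResidueLabelSet
from .structure_io import ProteinChain

logger = logging.getLogger(__name__)

__all__ = [
    "BindingCounts",
    "PropensityTable",
    "counts_from_labels",
    "compute_propensity",
    "bootstrap_errors",
    "compare_propensities",
]


@dataclass
class BindingCounts:
    """Binding / total residue counts per amino acid (canonical order)."""

    n_binding: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        self.n_binding = np.asarray(self.n_binding, dtype=np.int64)
        self.n_total = np.asarray(self.n_total, dtype=np.int64)
        if self.n_binding.shape != (20,) or self.n_total.shape != (20,):
            raise ValueError("counts must be 20-vectors in canonical amino-acid order")
        if np.any(self.n_binding > self.n_total) or np.any(self.n_binding < 0):
            raise ValueError("need 0 <= n_binding[aa] <= n_total[aa]")

    @property
    def n_binding_all(self) -> int:
        return int(self.n_binding.sum())

    @property
    def n_total_all(self) -> int:
        return int(self.n_total.sum())

    def __add__(self, other: "BindingCounts") -> "BindingCounts":
        return BindingCounts(self.n_binding + other.n_binding,
                             self.n_total + other.n_total)

    @classmethod
    def zero(cls) -> "BindingCounts":
        return cls(np.zeros(20, dtype=np.int64), np.zeros(20, dtype=np.int64))


@dataclass
class PropensityTable:
    """20 propensity values with optional bootstrap errors and raw counts."""

    p: np.ndarray
    counts: BindingCounts
    err: np.ndarray | None = None
    ligand_het: str = ""
    channel: str = "overall"
    meta: dict = field(default_factory=dict)

    def __getitem__(self, aa: str) -> float:
        return float(self.p[AA_INDEX[aa]])

    def to_tsv(self) -> str:
        lines = ["aa\tP\terr\tn_binding\tn_total"]
        err = self.err if self.err is not None else np.full(20, np.nan)
        for i, aa in enumerate(AA_ORDER):
            lines.append(
                f"{aa}\t{self.p[i]:.6g}\t{err[i]:.6g}\t"
                f"{self.counts.n_binding[i]}\t{self.counts.n_total[i]}"
            )
        return "\n".join(lines) + "\n"


def counts_from_labels(
    chain: ProteinChain, labels: ResidueLabelSet, channel: str = "overall"
) -> BindingCounts:
    """Tally binding/total counts for one protein, one channel.

    ``channel`` is ``"overall"`` or one of the four contact channels.
    Residues of unknown type (X) are excluded from the counts.
    """
    if channel == "overall":
        vec = labels.overall
    elif channel in CHANNELS:
        vec = labels.channels[channel]
    else:
        raise ValueError(f"unknown channel {channel!r}")
    counts = BindingCounts.zero()
    for res, is_binding in zip(chain.residues, vec):
        idx = AA_INDEX.get(res.residue_type)
        if idx is None:
            continue
        counts.n_total[idx] += 1
        if is_binding:
            counts.n_binding[idx] += 1
    return counts


def _propensity_vector(n_binding: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    nb_all = n_binding.sum()
    nt_all = n_total.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n_binding / n_total) * (nt_all / nb_all)
    return np.where(n_total > 0, p, np.nan)


def compute_propensity(
    counts: BindingCounts, ligand_het: str = "", channel: str = "overall"
) -> PropensityTable:
    """P(i) = (N_b(i)/N(i)) · (N(all)/N_b(all)); NaN where N(i) = 0."""
    if counts.n_total_all == 0:
        raise ValueError("empty dataset: no residues counted")
    if counts.n_binding_all == 0:
        raise ValueError("propensity undefined: no binding residues in dataset")
    absent = counts.n_total == 0
    if absent.any():
        logger.warning(
            "amino acids absent from dataset reported as NaN: %s",
            "".join(aa for aa, a in zip(AA_ORDER, absent) if a),
        )
    p = _propensity_vector(counts.n_binding.astype(float), counts.n_total.astype(float))
    return PropensityTable(p=p, counts=counts, ligand_het=ligand_het, channel=channel)


def bootstrap_errors(
    dataset: list[BindingCounts],
    n_replicates: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap SD of the propensity over protein-level resampling.

    Each pseudo-copy draws ``len(dataset)`` proteins with replacement,
    pools their counts and recomputes the 20 propensities; the error bar
    is the population standard deviation across pseudo-copies.
    Pseudo-copies with no binding residues at all are excluded (their
    count is logged); amino acids absent from a pseudo-copy contribute
    NaN to that replicate and are likewise ignored in its SD.
    """
    if not dataset:
        raise ValueError("bootstrap needs at least one protein")
    nb = np.array([c.n_binding for c in dataset])  # (n_prot, 20)
    nt = np.array([c.n_total for c in dataset])
    n_prot = len(dataset)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_prot, size=(n_replicates, n_prot))
    reps = np.full((n_replicates, 20), np.nan)
    n_degenerate = 0
    for r in range(n_replicates):
        nb_pool = nb[draws[r]].sum(axis=0)
        nt_pool = nt[draws[r]].sum(axis=0)
        if nb_pool.sum() == 0:
            n_degenerate += 1
            continue
        reps[r] = _propensity_vector(nb_pool.astype(float), nt_pool.astype(float))
    if n_degenerate:
        logger.info("%d/%d bootstrap replicates had no binding residues; excluded",
                    n_degenerate, n_replicates)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        err = np.nanstd(reps, axis=0, ddof=0)  # population SD
        # identical replicates (e.g. a single-protein dataset) are exactly
        # zero-variance; avoid reporting mean-subtraction round-off instead
        degenerate = np.nanmax(reps, axis=0) == np.nanmin(reps, axis=0)
    err[degenerate & np.isfinite(err)] = 0.0
    return err


def compare_propensities(a: PropensityTable, b: PropensityTable) -> tuple[float, float]:
    """Pearson correlation (r, r²) over amino acids finite in both tables."""
    mask = np.isfinite(a.p) & np.isfinite(b.p)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 amino acids with finite propensity in both tables, got {int(mask.sum())}"
        )
    r = stats.pearsonr(a.p[mask], b.p[mask]).statistic
    return float(r), float(r * r)
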