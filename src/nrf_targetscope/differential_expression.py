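"""Per-gene differential expression for overexpression-vs-vector designs.

The primary statistic is the two-sample unequal-variance (Welch) t-test with
Welch-Satterthwaite degrees of freedom, applied to log2(abundance + pseudocount)
so that the tested contrast is consistent with the reported log2 fold change.
Significance calling uses raw p-values with an absolute log2-fold-change floor
(defaults p < 0.05, |log2FC| > 0.075, both strict); Benjamini-Hochberg q-values
are attached as an informational column but do not gate the calls.

Also provided: the "active transcriptome" expression filter and the comparative
Ct (delta-delta-Ct) utility for qPCR relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Variance floor applied to the squared standard error of the mean difference
#: when both groups are (numerically) constant; keeps degenerate genes in the
#: output instead of dropping them.
VARIANCE_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """Significance-calling thresholds.

    Parameters
    ----------
    p_max
        Raw two-sided p-value cutoff (strict inequality).
    min_abs_log2fc
        Absolute log2-fold-change floor (strict inequality).
    min_expression
        Active-transcriptome filter: a gene is retained when its maximum
        abundance across all samples exceeds this value.
    pseudocount
        Abundance added before any log2 transform (fold change and test scale).
    """

    p_max: float = 0.05
    min_abs_log2fc: float = 0.075
    min_expression: float = 0.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError(f"p_max must lie in (0, 1], got {self.p_max}")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.min_expression < 0:
            raise ValueError("min_expression must be >= 0")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix (RPKM-like, nonnegative) plus design.

    ``design`` is indexed by sample id; for two-condition experiments it
    carries columns ``group``/``replicate``, for tissue panels
    ``tissue``/``donor``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = pd.Index(self.gene_ids).duplicated()
        if dup.any():
            dupes = sorted({g for g, d in zip(self.gene_ids, dup) if d})
            raise ValueError(f"duplicate gene IDs: {', '.join(dupes[:5])}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = set(self.sample_ids) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_columns(self, label: str, column: str = "group") -> np.ndarray:
        """Column indices of samples whose design ``column`` equals ``label``."""
        members = set(self.design.index[self.design[column] == label])
        idx = np.array([i for i, s in enumerate(self.sample_ids) if s in members])
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DifferentialResult:
    """Per-gene Welch-test outcome for alt (e.g. overexpression) vs ref (vector)."""

    gene_id: str
    mean_ref: float
    mean_alt: float
    log2fc: float
    t_stat: float
    df: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    direction: str = "none"
    degenerate: bool = field(default=False, repr=False)


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------


def welch_t_test_arrays(
    ref: np.ndarray, alt: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test over rows of two (genes x replicates) arrays.

    Returns ``(t, df, p, degenerate)`` where ``t`` is signed alt-minus-ref.
    Rows in which both groups are constant are flagged degenerate: the squared
    standard error is floored at :data:`VARIANCE_FLOOR` (equal means still
    yield t = 0, p = 1) and df falls back to the pooled n - 2.
    """
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    alt = np.atleast_2d(np.asarray(alt, dtype=float))
    na, nb = ref.shape[1], alt.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(ref).all() and np.isfinite(alt).all()):
        raise ValueError("groups must contain only finite values")

    va = ref.var(axis=1, ddof=1)
    vb = alt.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    degenerate = se2 <= VARIANCE_FLOOR
    se2 = np.maximum(se2, VARIANCE_FLOOR)
    t = (alt.mean(axis=1) - ref.mean(axis=1)) / np.sqrt(se2)

    denom = sa**2 / (na - 1) + sb**2 / (nb - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / denom
    df = np.where(denom > 0, df, na + nb - 2.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p, degenerate


def welch_t_test(
    group_ref: Sequence[float], group_alt: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t_stat, df, p_value)``.

    The t statistic is signed alt minus ref, matching the sign of the log2
    fold change of alt over ref.
    """
    t, df, p, _ = welch_t_test_arrays(
        np.asarray(group_ref, dtype=float)[None, :],
        np.asarray(group_alt, dtype=float)[None, :],
    )
    return float(t[0]), float(df[0]), float(p[0])


# ---------------------------------------------------------------------------
# Fold change and filters
# ---------------------------------------------------------------------------


def compute_log2fc(mean_ref: float, mean_alt: float, pseudocount: float = 1.0) -> float:
    """log2((mean_alt + pseudocount) / (mean_ref + pseudocount))."""
    if mean_ref < 0 or mean_alt < 0:
        raise ValueError("means must be nonnegative")
    if mean_ref + pseudocount == 0 or mean_alt + pseudocount == 0:
        raise ValueError("log2 fold change undefined: zero mean with zero pseudocount")
    return float(np.log2((mean_alt + pseudocount) / (mean_ref + pseudocount)))


def active_transcriptome_filter(
    matrix: ExpressionMatrix, min_expression: float = 0.0
) -> list[str]:
    """Genes whose maximum abundance over all samples exceeds ``min_expression``.

    Input gene order is preserved; a fully silent gene never passes when
    ``min_expression`` is 0 (the comparison is strict).
    """
    keep = matrix.values.max(axis=1) > min_expression
    dropped = int((~keep).sum())
    if dropped:
        logger.info("active filter removed %d/%d genes (reason=below_min_expression)",
                    dropped, matrix.n_genes)
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


# ---------------------------------------------------------------------------
# Significance calling
# ---------------------------------------------------------------------------


def call_differential(
    matrix: ExpressionMatrix,
    ref_group: str,
    alt_group: str,
    thresholds: Thresholds = Thresholds(),
) -> list[DifferentialResult]:
    """Welch-test every active gene of ``alt_group`` vs ``ref_group``.

    Tests are run on log2(abundance + pseudocount); fold changes are computed
    from the raw group means with the same pseudocount. A gene is significant
    iff p < p_max and |log2FC| > min_abs_log2fc (both strict). The output is
    aligned with (and ordered like) the active-filtered input gene list.
    """
    for grp in (ref_group, alt_group):
        if grp not in set(matrix.design["group"]):
            raise ValueError(f"group {grp!r} not present in design")
    ref_idx = matrix.group_columns(ref_group)
    alt_idx = matrix.group_columns(alt_group)
    if len(ref_idx) < 2 or len(alt_idx) < 2:
        raise ValueError("each group needs >= 2 replicates")

    active = active_transcriptome_filter(matrix, thresholds.min_expression)
    active_set = set(active)
    rows = np.array([i for i, g in enumerate(matrix.gene_ids) if g in active_set])
    if rows.size == 0:
        return []
    vals = matrix.values[rows]
    ref_vals = vals[:, ref_idx]
    alt_vals = vals[:, alt_idx]

    pc = thresholds.pseudocount
    t, df, p, degen = welch_t_test_arrays(np.log2(ref_vals + pc), np.log2(alt_vals + pc))
    mean_ref = ref_vals.mean(axis=1)
    mean_alt = alt_vals.mean(axis=1)
    lfc = np.log2((mean_alt + pc) / (mean_ref + pc))
    q = multipletests(p, method="fdr_bh")[1]
    sig = (p < thresholds.p_max) & (np.abs(lfc) > thresholds.min_abs_log2fc)

    if degen.any():
        logger.info("%d genes flagged degenerate (reason=zero_variance_floor)",
                    int(degen.sum()))

    results = []
    for j, g in enumerate(active):
        direction = "none"
        if sig[j]:
            direction = "up" if lfc[j] > 0 else "down"
        results.append(
            DifferentialResult(
                gene_id=g,
                mean_ref=float(mean_ref[j]),
                mean_alt=float(mean_alt[j]),
                log2fc=float(lfc[j]),
                t_stat=float(t[j]),
                df=float(df[j]),
                p_value=float(p[j]),
                q_value=float(q[j]),
                significant=bool(sig[j]),
                direction=direction,
                degenerate=bool(degen[j]),
            )
        )
    return results


def differential_table(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """DE results as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "mean_ref": [r.mean_ref for r in results],
            "mean_alt": [r.mean_alt for r in results],
            "log2fc": [r.log2fc for r in results],
            "t": [r.t_stat for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Comparative Ct (qPCR)
# ---------------------------------------------------------------------------


def delta_delta_ct(
    ct_target: Mapping[str, Sequence[float]],
    ct_reference: Mapping[str, Sequence[float]],
    control_label: str,
) -> dict[str, float]:
    """Relative transcript abundance by the comparative Ct method.

    Per condition, dCt = mean(Ct_target) - mean(Ct_reference); ddCt subtracts
    the control condition's dCt; relative abundance = 2**(-ddCt), so the
    control maps to exactly 1.
    """
    if control_label not in ct_target:
        raise ValueError(f"control condition {control_label!r} missing")
    if set(ct_target) != set(ct_reference):
        raise ValueError("target and reference Ct tables list different conditions")
    dct = {
        cond: float(np.mean(ct_target[cond])) - float(np.mean(ct_reference[cond]))
        for cond in ct_target
    }
    control_dct = dct[control_label]
    return {cond: float(2.0 ** (-(d - control_dct))) for cond, d in dct.items()}
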