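"""Cross-study consensus gene sets and fold-change concordance.

Builds tiered consensus sets from two differential-expression studies and a
protein quantification table: genes significant in both studies in the same
direction (shared RNA up/down), and the subset whose protein levels also
change significantly (RNA + Protein). Concordance between studies, or between
RNA and protein fold changes, is summarized by ordinary least squares with the
r-squared of the free-intercept fit (the squared Pearson correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import DifferentialResult, Thresholds
from .enrichment import GeneSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class StudyComparison:
    """OLS summary of lfc_b on lfc_a over the shared genes."""

    shared_genes: list[str]
    lfc_a: np.ndarray
    lfc_b: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)


class IntersectionResult(NamedTuple):
    """Directional split of two studies' significant calls.

    The five sets partition the union of significant genes: shared_up and
    shared_down (significant in both, concordant when required), a_only /
    b_only (significant in exactly one study), and discordant (significant in
    both with opposite signs while concordance is required).
    """

    shared_up: set[str]
    shared_down: set[str]
    a_only: set[str]
    b_only: set[str]
    discordant: set[str]


@dataclass
class ConsensusSets:
    rna_up: set[str]
    rna_down: set[str]
    rna_protein: set[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.rna_up & self.rna_down:
            raise ValueError("rna_up and rna_down overlap")
        if not self.rna_protein <= (self.rna_up | self.rna_down):
            raise ValueError("rna_protein must be nested in rna_up | rna_down")


# ---------------------------------------------------------------------------
# Table normalization
# ---------------------------------------------------------------------------


def _normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Accept (gene, log2FC, p) with flexible column case; upper-case genes."""
    cols = {c.lower(): c for c in table.columns}
    try:
        gene_c, lfc_c, p_c = cols["gene"], cols.get("log2fc", cols.get("lfc")), cols["p"]
    except KeyError as exc:
        raise ValueError(f"differential table missing column: {exc}") from exc
    if lfc_c is None:
        raise ValueError("differential table missing column: log2FC")
    out = table[[gene_c, lfc_c, p_c]].copy()
    out.columns = ["gene", "log2FC", "p"]
    out["gene"] = out["gene"].astype(str).str.upper()
    return out


def _significant_calls(table: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    sig = (table["p"] < thresholds.p_max) & (
        table["log2FC"].abs() > thresholds.min_abs_log2fc
    )
    return table[sig]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def intersect_de(
    study_a: Sequence[DifferentialResult],
    study_b: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    require_sign_concordance: bool = True,
) -> IntersectionResult:
    """Split two studies' significant genes into shared/specific sets.

    Study A is this pipeline's DE output (its ``significant`` flags are used);
    study B is an external (gene, log2FC, p) table thresholded with the same
    rule. Gene symbols are matched case-insensitively.
    """
    a_up = {r.gene_id.upper() for r in study_a if r.significant and r.direction == "up"}
    a_down = {r.gene_id.upper() for r in study_a if r.significant and r.direction == "down"}

    b = _significant_calls(_normalize_table(study_b), thresholds)
    b_up = set(b.loc[b["log2FC"] > 0, "gene"])
    b_down = set(b.loc[b["log2FC"] < 0, "gene"])

    a_sig, b_sig = a_up | a_down, b_up | b_down
    if require_sign_concordance:
        shared_up = a_up & b_up
        shared_down = a_down & b_down
        discordant = (a_sig & b_sig) - shared_up - shared_down
    else:
        shared_up = a_up & b_sig
        shared_down = a_down & b_sig
        discordant = set()
    if not (shared_up or shared_down):
        logger.warning("no shared significant genes between the two studies")
    return IntersectionResult(
        shared_up=shared_up,
        shared_down=shared_down,
        a_only=a_sig - b_sig,
        b_only=b_sig - a_sig,
        discordant=discordant,
    )


def regress_fold_changes(
    lfc_a: Sequence[float],
    lfc_b: Sequence[float],
    shared_genes: Sequence[str] | None = None,
) -> StudyComparison:
    """OLS of lfc_b on lfc_a; r-squared is the squared Pearson correlation.

    r-squared is symmetric in the two studies; the slope is not (it answers
    "how much does study B move per log2 unit in study A").
    """
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if a.size != b.size:
        raise ValueError("fold-change vectors must be aligned")
    if a.size < 3:
        raise ValueError("need >= 3 shared genes for regression")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in predictor fold changes; slope undefined")
    fit = stats.linregress(a, b)
    genes = list(shared_genes) if shared_genes is not None else [
        f"pair_{i}" for i in range(a.size)
    ]
    return StudyComparison(
        shared_genes=genes,
        lfc_a=a,
        lfc_b=b,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def build_consensus(
    shared_up: set[str],
    shared_down: set[str],
    protein_table: pd.DataFrame | None,
    thresholds: Thresholds = Thresholds(),
    require_protein_sign_concordance: bool = True,
) -> ConsensusSets:
    """Tiered consensus sets: shared RNA up/down plus the protein-backed subset.

    ``rna_protein`` keeps shared genes whose protein p < p_max (same cutoff as
    RNA; no separate protein fold-change floor) and, when required, whose
    protein fold-change sign matches the RNA direction.
    """
    shared_up = {g.upper() for g in shared_up}
    shared_down = {g.upper() for g in shared_down}
    records: list[dict] = []
    rna_protein: set[str] = set()

    if protein_table is None or len(protein_table) == 0:
        logger.warning("no protein table provided; rna_protein tier left empty")
        prot = pd.DataFrame(columns=["gene", "log2FC", "p"])
    else:
        prot = _normalize_table(protein_table)
    prot_map = prot.set_index("gene")[["log2FC", "p"]].to_dict("index")

    for g in sorted(shared_up | shared_down):
        direction = "up" if g in shared_up else "down"
        rec = {
            "gene": g,
            "rna_direction": direction,
            "protein_log2FC": float("nan"),
            "protein_p": float("nan"),
            "protein_direction": "none",
            "in_rna_protein": False,
        }
        entry = prot_map.get(g)
        if entry is not None:
            rec["protein_log2FC"] = float(entry["log2FC"])
            rec["protein_p"] = float(entry["p"])
            if entry["p"] < thresholds.p_max:
                prot_dir = "up" if entry["log2FC"] > 0 else "down"
                rec["protein_direction"] = prot_dir
                if not require_protein_sign_concordance or prot_dir == direction:
                    rna_protein.add(g)
                    rec["in_rna_protein"] = True
        records.append(rec)

    return ConsensusSets(
        rna_up=shared_up,
        rna_down=shared_down,
        rna_protein=rna_protein,
        provenance=pd.DataFrame(records),
    )


def export_gene_sets(sets: ConsensusSets, collection_name: str) -> list[GeneSet]:
    """Consensus tiers as GeneSet records (one GMT line each); empty tiers omitted."""
    tiers = {
        f"{collection_name}_up": (sets.rna_up, "shared RNA upregulated"),
        f"{collection_name}_down": (sets.rna_down, "shared RNA downregulated"),
        f"{collection_name}_rna_protein": (
            sets.rna_protein,
            "shared RNA, protein-level concordant",
        ),
    }
    out = []
    for name, (members, desc) in tiers.items():
        if not members:
            logger.info("tier %r empty; omitted from GMT export", name)
            continue
        out.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return out
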