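"""Synthetic inputs with planted ground truth for the whole pipeline.

Emulates the study designs the pipeline consumes, without any downloads:

* a two-condition (vector vs overexpression) triplicate expression matrix with
  a planted fraction of differentially expressed genes,
* a companion study's differential table that corroborates a controllable
  fraction of the planted genes,
* a protein-level quantification table whose fold changes are an attenuated,
  noisy copy of the planted RNA effects,
* multi-tissue expression panels with planted coherent / anti-correlated /
  background co-expression modules driven by a donor-level latent factor.

Everything is simulated on the log2 scale and exponentiated, so abundances are
RPKM-like and strictly positive, and every operation is a pure function of its
arguments and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Nominal standard error used to convert a null z-draw into a (log2FC, p)
#: pair for genes that are not called: p = 2*sf(|z|) is Uniform(0,1) while
#: |log2FC| = 0.01*|z| essentially never crosses a 0.075 fold-change floor.
NULL_LFC_SE = 0.01

#: Floor on the standard error of the "implied test" that converts a called
#: gene's log2FC into a p-value, so noise-free calls still get finite z.
CALL_SE_FLOOR = 0.05

#: Fraction of null genes reported as study-specific (decoy) calls by the
#: companion study.
DECOY_FRACTION = 0.02


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the two-condition overexpression simulation.

    Defaults reproduce the triplicate design with a 10% planted DE fraction
    and ~1.5 log2-unit effects used throughout the test-bench.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    de_fraction: float = 0.1
    effect_mean: float = 1.5
    effect_sd: float = 0.25
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.5
    replicate_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        for name in ("effect_sd", "baseline_log_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "de_fraction", "effect_mean", "effect_sd", "baseline_log_mean",
            "baseline_log_sd", "replicate_noise_sd",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators.

    ``de_effects`` maps each planted gene to its signed true log2 effect;
    ``module_assignment`` maps tissue -> gene -> module label
    (``coherent`` / ``anti`` / ``background``).
    """

    gene_ids: list[str] = field(default_factory=list)
    de_effects: dict[str, float] = field(default_factory=dict)
    protein_attenuation: float | None = None
    module_assignment: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de_effects)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _implied_p(lfc: np.ndarray, se: float) -> np.ndarray:
    """Two-sided normal p-value implied by a fold change at standard error se."""
    z = np.abs(lfc) / max(se, CALL_SE_FLOOR)
    return 2.0 * stats.norm.sf(z)


def _null_entries(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated null (log2FC, p) pairs: p is Uniform(0,1), |log2FC| tiny."""
    z = rng.standard_normal(n)
    return z * NULL_LFC_SE, 2.0 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# Two-condition overexpression experiment
# ---------------------------------------------------------------------------


def simulate_overexpression(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a vector-vs-overexpression triplicate experiment.

    Per gene, abundance = 2**(baseline + condition_effect + noise) with
    baseline ~ N(baseline_log_mean, baseline_log_sd), condition_effect equal
    to the planted signed effect in overexpression samples of DE genes and 0
    otherwise, and i.i.d. N(0, replicate_noise_sd) noise per cell. Effect
    signs are Bernoulli(1/2); magnitudes ~ N(effect_mean, effect_sd).
    """
    rng = np.random.default_rng(params.seed)
    genes = _gene_ids(params.n_genes)
    n_de = int(round(params.de_fraction * params.n_genes))
    de_idx = rng.choice(params.n_genes, size=n_de, replace=False)
    magnitudes = rng.normal(params.effect_mean, params.effect_sd, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(params.n_genes)
    effects[de_idx] = signs * magnitudes

    nrep = params.n_replicates
    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd,
                          size=params.n_genes)
    log2x = np.tile(baseline[:, None], (1, 2 * nrep))
    log2x[:, nrep:] += effects[:, None]
    log2x += rng.normal(0.0, params.replicate_noise_sd, size=log2x.shape)
    values = 2.0 ** log2x

    sample_ids = [f"vector_{i + 1}" for i in range(nrep)] + [
        f"overexpression_{i + 1}" for i in range(nrep)
    ]
    design = pd.DataFrame(
        {
            "group": ["vector"] * nrep + ["overexpression"] * nrep,
            "replicate": list(range(1, nrep + 1)) * 2,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    matrix = ExpressionMatrix(genes, sample_ids, values, design)
    truth = SyntheticTruth(
        gene_ids=genes,
        de_effects={genes[i]: float(effects[i]) for i in de_idx},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Companion study
# ---------------------------------------------------------------------------


def simulate_companion_study(
    truth: SyntheticTruth,
    overlap_fraction: float,
    fc_noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Differential table (gene, log2FC, p) of a partially overlapping study.

    A fraction ``overlap_fraction`` of the planted DE genes is reported
    significant with log2FC = true effect + N(0, fc_noise_sd) and a p-value
    implied by that fold change. Study-specific (decoy) calls are drawn from
    2% of the null genes; every other gene receives a calibrated null entry.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if fc_noise_sd < 0:
        raise ValueError("fc_noise_sd must be >= 0")
    if not truth.de_effects:
        logger.warning("companion study: truth has no DE genes; returning empty table")
        return pd.DataFrame(columns=["gene", "log2FC", "p"])

    rng = np.random.default_rng(seed)
    genes = list(truth.gene_ids)
    de_genes = sorted(truth.de_effects)
    null_genes = sorted(set(genes) - set(de_genes))

    n_overlap = int(round(overlap_fraction * len(de_genes)))
    shared = set(rng.choice(de_genes, size=n_overlap, replace=False)) if n_overlap else set()
    n_decoy = int(round(DECOY_FRACTION * len(null_genes)))
    decoys = set(rng.choice(null_genes, size=n_decoy, replace=False)) if n_decoy else set()

    lfc = np.empty(len(genes))
    p = np.empty(len(genes))
    null_lfc, null_p = _null_entries(rng, len(genes))
    # Effect magnitudes for decoys mirror the planted effect distribution.
    for i, g in enumerate(genes):
        if g in shared:
            val = truth.de_effects[g] + (rng.normal(0.0, fc_noise_sd) if fc_noise_sd else 0.0)
            lfc[i] = val
            p[i] = _implied_p(np.array([val]), fc_noise_sd)[0]
        elif g in decoys:
            val = rng.choice([-1.0, 1.0]) * rng.normal(1.5, 0.25)
            lfc[i] = val
            p[i] = _implied_p(np.array([val]), fc_noise_sd)[0]
        else:
            lfc[i] = null_lfc[i]
            p[i] = null_p[i]
    return pd.DataFrame({"gene": genes, "log2FC": lfc, "p": p})


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------


def simulate_proteome(
    truth: SyntheticTruth,
    attenuation: float,
    coverage: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Protein quantification table (gene, log2FC, p).

    Each gene is detected independently with probability ``coverage``.
    Detected planted genes get protein log2FC = attenuation * RNA effect +
    N(0, noise_sd) with a p-value implied by the fold change; detected null
    genes get calibrated null entries. Records ``attenuation`` on the truth.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    if not math.isfinite(attenuation):
        raise ValueError("attenuation must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    genes = list(truth.gene_ids)
    detected = rng.random(len(genes)) < coverage
    null_lfc, null_p = _null_entries(rng, len(genes))

    rows = []
    for i, g in enumerate(genes):
        if not detected[i]:
            continue
        if g in truth.de_effects:
            val = attenuation * truth.de_effects[g]
            if noise_sd:
                val += rng.normal(0.0, noise_sd)
            rows.append((g, val, float(_implied_p(np.array([val]), noise_sd)[0])))
        else:
            rows.append((g, float(null_lfc[i]), float(null_p[i])))
    truth.protein_attenuation = float(attenuation)
    return pd.DataFrame(rows, columns=["gene", "log2FC", "p"])


# ---------------------------------------------------------------------------
# Multi-tissue co-expression panels
# ---------------------------------------------------------------------------

DEFAULT_TISSUES = ("brain", "liver", "heart")


def simulate_tissue_panel(
    gene_set: list[str],
    n_tissues: int = 3,
    n_donors: int = 200,
    r_within: float = 0.9,
    anti_loading: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    frac_coherent: float = 1.0 / 3.0,
    frac_anti: float = 1.0 / 3.0,
    baseline_log_mean: float = 10.0,
    baseline_log_sd: float = 1.0,
) -> tuple[dict[str, ExpressionMatrix], SyntheticTruth]:
    """Per-tissue expression panels with planted co-expression modules.

    A donor-level latent factor f ~ N(0,1) drives log2 expression:
    coherent-module genes load +lambda, anti-module genes -anti_loading*lambda,
    background genes 0, with lambda = noise_sd*sqrt(r/(1-r)) so the expected
    pairwise correlation within the coherent module is ``r_within``. Module
    membership is re-drawn independently per tissue, so cross-tissue
    assignments differ — the feature the downstream cross-tissue comparison
    is designed to expose.
    """
    if n_donors < 3:
        raise ValueError("n_donors must be >= 3")
    if not (0.0 < r_within < 1.0):
        raise ValueError("r_within must lie in (0, 1)")
    if frac_coherent < 0 or frac_anti < 0 or frac_coherent + frac_anti > 1:
        raise ValueError("module fractions must be nonnegative and sum to <= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")

    genes = list(gene_set)
    n = len(genes)
    lam = noise_sd * math.sqrt(r_within / (1.0 - r_within))
    n_coh = int(round(frac_coherent * n))
    n_anti = int(round(frac_anti * n))

    root = np.random.SeedSequence(seed)
    tissue_seeds = root.spawn(n_tissues)
    tissues = [
        DEFAULT_TISSUES[t] if t < len(DEFAULT_TISSUES) else f"tissue_{t + 1}"
        for t in range(n_tissues)
    ]

    panels: dict[str, ExpressionMatrix] = {}
    truth = SyntheticTruth(gene_ids=genes)
    for tissue, ss in zip(tissues, tissue_seeds):
        rng = np.random.default_rng(ss)
        order = rng.permutation(n)
        labels = np.full(n, "background", dtype=object)
        labels[order[:n_coh]] = "coherent"
        labels[order[n_coh:n_coh + n_anti]] = "anti"
        loading = np.where(
            labels == "coherent", lam,
            np.where(labels == "anti", -anti_loading * lam, 0.0),
        ).astype(float)

        baseline = rng.normal(baseline_log_mean, baseline_log_sd, size=n)
        f = rng.standard_normal(n_donors)
        log2x = (
            baseline[:, None]
            + loading[:, None] * f[None, :]
            + rng.normal(0.0, noise_sd, size=(n, n_donors))
        )
        donors = [f"{tissue}_donor_{d + 1}" for d in range(n_donors)]
        design = pd.DataFrame(
            {"tissue": [tissue] * n_donors, "donor": list(range(1, n_donors + 1))},
            index=pd.Index(donors, name="sample"),
        )
        panels[tissue] = ExpressionMatrix(genes, donors, 2.0 ** log2x, design)
        truth.module_assignment[tissue] = {g: str(l) for g, l in zip(genes, labels)}
    return panels, truth
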