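"""Residual-variation modelling and term-enrichment statistics.

The raw variant count of a contig confounds genetic variation with
detection power: long, deeply covered contigs yield more calls.  The
residual model regresses the per-contig variant count on log10 contig
length and log10 read number by ordinary least squares; the residual
(observed minus fitted) is the power-corrected variation estimate.

Residuals are then averaged onto expression-array constructs (a
construct matching several contigs gets the mean residual), regressed on
four expression covariates (overall expression level "A", number of
tissues expressed, morph-biased and sex-biased expression), and the
extreme tails of the residual distribution are tested for annotation-term
enrichment with a one-sided Fisher exact test, Benjamini-Hochberg
corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContigCovariates",
    "ResidualRecord",
    "ResidualModelResult",
    "ExpressionRecord",
    "EnrichmentResult",
    "fit_residual_model",
    "compute_residuals",
    "map_array_units",
    "fit_expression_model",
    "select_extremes",
    "fisher_enrichment",
]


@dataclass(frozen=True)
class ContigCovariates:
    contig_id: str
    length_bp: int
    n_reads: int
    n_snp: int
    n_indel: int

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"contig {self.contig_id}: length must be >= 1")
        if min(self.n_reads, self.n_snp, self.n_indel) < 0:
            raise ValueError(f"contig {self.contig_id}: negative count")


@dataclass
class ResidualRecord:
    contig_id: str
    residual_snp: float
    residual_indel: float


@dataclass
class ResidualModelResult:
    response: str
    terms: pd.DataFrame  # term, estimate, F, p
    residuals: dict[str, float]
    fitted: "sm.regression.linear_model.RegressionResultsWrapper"


@dataclass(frozen=True)
class ExpressionRecord:
    unit_id: str
    avg_expression: float
    n_tissues: int
    morph_bias: float
    sex_bias: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_tissues <= 4:
            raise ValueError(f"unit {self.unit_id}: n_tissues must be in [0, 4]")


@dataclass
class EnrichmentResult:
    term_id: str
    study_hits: int
    study_size: int
    pop_hits: int
    pop_size: int
    p_value: float
    fdr: float


def _check_design(X: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"degenerate design in {what}: collinear or constant predictors")


def fit_residual_model(
    covariates: Sequence[ContigCovariates],
    response: str = "snp",
    log_response: bool = False,
) -> ResidualModelResult:
    """OLS of per-contig variant count on log10(length) and log10(reads).

    The default response is the raw count; ``log_response=True`` fits
    log1p(count) instead.  Per-term F statistics are the partial F with
    one numerator degree of freedom (the squared t statistic).
    """
    if response not in ("snp", "indel"):
        raise ValueError("response must be 'snp' or 'indel'")
    if len(covariates) < 3:
        raise ValueError("need at least 3 contigs to fit the residual model")
    y = np.array(
        [c.n_snp if response == "snp" else c.n_indel for c in covariates], dtype=float
    )
    if log_response:
        y = np.log1p(y)
    X = np.column_stack(
        [
            np.log10([c.length_bp for c in covariates]),
            np.log10([max(c.n_reads, 1) for c in covariates]),
        ]
    )
    X = sm.add_constant(X, has_constant="add")
    _check_design(X, "residual model")
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "log10_length", "log10_reads"]
    terms = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params,
            "F": fit.tvalues**2,
            "p": fit.pvalues,
        }
    )
    residuals = {
        c.contig_id: float(r) for c, r in zip(covariates, fit.resid)
    }
    return ResidualModelResult(
        response=response, terms=terms, residuals=residuals, fitted=fit
    )


def compute_residuals(
    covariates: Sequence[ContigCovariates], log_response: bool = False
) -> list[ResidualRecord]:
    """Fit both responses and collect per-contig residual records."""
    snp = fit_residual_model(covariates, "snp", log_response)
    indel = fit_residual_model(covariates, "indel", log_response)
    return [
        ResidualRecord(
            contig_id=c.contig_id,
            residual_snp=snp.residuals[c.contig_id],
            residual_indel=indel.residuals[c.contig_id],
        )
        for c in covariates
    ]


def map_array_units(
    residuals: Sequence[ResidualRecord],
    mapping: Mapping[str, Sequence[str]],
) -> dict[str, ResidualRecord]:
    """Average contig residuals onto array constructs.

    A unit matching several contigs gets the arithmetic mean residual;
    units matching none are absent from the output.
    """
    by_contig = {r.contig_id: r for r in residuals}
    out: dict[str, ResidualRecord] = {}
    for unit, contigs in mapping.items():
        for cid in contigs:
            if cid not in by_contig:
                raise KeyError(f"unit {unit} maps to unknown contig {cid}")
        if not contigs:
            continue
        out[unit] = ResidualRecord(
            contig_id=unit,
            residual_snp=float(np.mean([by_contig[c].residual_snp for c in contigs])),
            residual_indel=float(np.mean([by_contig[c].residual_indel for c in contigs])),
        )
    return out


_EXPR_TERMS = ["avg_expression", "n_tissues", "morph_bias", "sex_bias"]


def fit_expression_model(
    unit_residuals: Mapping[str, ResidualRecord],
    expression: Sequence[ExpressionRecord],
    response: str = "snp",
) -> pd.DataFrame:
    """OLS of unit residuals on the four expression covariates.

    Returns a per-term table (estimate, partial F with 1 numerator df,
    p) for units present in both inputs.
    """
    if response not in ("snp", "indel"):
        raise ValueError("response must be 'snp' or 'indel'")
    records = [e for e in expression if e.unit_id in unit_residuals]
    if len(records) < 6:
        raise ValueError("need at least 6 matched units")
    y = np.array(
        [
            unit_residuals[e.unit_id].residual_snp
            if response == "snp"
            else unit_residuals[e.unit_id].residual_indel
            for e in records
        ]
    )
    X = np.column_stack(
        [
            [e.avg_expression for e in records],
            [e.n_tissues for e in records],
            [e.morph_bias for e in records],
            [e.sex_bias for e in records],
        ]
    )
    X = sm.add_constant(X, has_constant="add")
    _check_design(X, "expression model")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "term": ["intercept"] + _EXPR_TERMS,
            "estimate": fit.params,
            "F": fit.tvalues**2,
            "p": fit.pvalues,
        }
    )


def select_extremes(
    unit_residuals: Mapping[str, float], fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Top and bottom ``fraction`` of units by residual.

    Set sizes are floor(fraction * n); boundary ties are broken by unit
    id (lexicographically smaller wins).
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = len(unit_residuals)
    k = math.floor(fraction * n)
    if k == 0:
        warnings.warn("too few units for a nonempty extreme set", stacklevel=2)
        return [], []
    top = sorted(unit_residuals, key=lambda u: (-unit_residuals[u], u))[:k]
    bottom = sorted(unit_residuals, key=lambda u: (unit_residuals[u], u))[:k]
    return top, bottom


def fisher_enrichment(
    study: set[str],
    population: set[str],
    annotations: Mapping[str, set[str]],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Per-term Fisher exact enrichment of a study set within a population.

    One-sided (enrichment) by default; terms with no population hits are
    skipped.  FDR is Benjamini-Hochberg across the tested terms.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    pop_size, study_size = len(population), len(study)
    rows = []
    for term in sorted(annotations):
        ids = annotations[term] & population
        pop_hits = len(ids)
        if pop_hits == 0:
            continue
        study_hits = len(ids & study)
        table = [
            [study_hits, study_size - study_hits],
            [pop_hits - study_hits, (pop_size - study_size) - (pop_hits - study_hits)],
        ]
        _, p = fisher_exact(table, alternative=alternative)
        rows.append((term, study_hits, pop_hits, float(p)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term_id=term,
            study_hits=sh,
            study_size=study_size,
            pop_hits=ph,
            pop_size=pop_size,
            p_value=p,
            fdr=float(f),
        )
        for (term, sh, ph, p), f in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
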