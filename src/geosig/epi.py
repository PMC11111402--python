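"""Epidemiological association and clonal-timing statistics.

Implements the statistical layer applied downstream of attribution:
CI-based dichotomization of signature activities (with a median split for
near-ubiquitous signatures), risk-factor logistic regressions adjusted for
sex, age at diagnosis, country and tobacco status, linear regressions of
burdens/attributions on country-level age-standardized incidence rates
(ASR), cross-country burden comparison, the clonal/subclonal filtering and
paired enrichment test, and driver-spectrum enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .attribution import AttributionResults, PenaltyConfig, _point_attribution
from .catalogue import CatalogueMatrix
from .decomposition import SignatureMatrix


@dataclass
class TestResult:
    """One statistical comparison: term, effect estimate, p (and q) value."""

    term: str
    estimate: float
    p_value: float
    n: int
    q_value: float | None = None
    family_size: int | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# dichotomization and regressions


def dichotomize(
    attr: AttributionResults, prevalence_threshold: float = 0.75
) -> pd.DataFrame:
    """Binary per-sample outcomes from attribution results.

    Signatures present (CI excluding zero at both limits) in at least
    ``prevalence_threshold`` of cases are split at the median of attributed
    mutation counts over all cases; rarer signatures are coded by the CI
    presence rule itself.
    """
    presence = attr.presence_matrix()
    exposures = attr.exposure_matrix()
    out = {}
    for sig in presence.index:
        prev = presence.loc[sig].mean()
        if prev >= prevalence_threshold:
            med = exposures.loc[sig].median()
            out[sig] = (exposures.loc[sig] > med).astype(int)
        else:
            out[sig] = presence.loc[sig].astype(int)
    return pd.DataFrame(out, index=presence.columns)


DEFAULT_COVARIATES = ("sex", "age_dx", "country", "smoking")


def risk_factor_regression(
    data: pd.DataFrame,
    outcome: str,
    factor: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    family_size: int | None = None,
) -> TestResult:
    """Logistic regression of a binary signature outcome on a risk factor.

    Covariates enter as factorized terms where non-numeric. Reports the
    Wald estimate (log odds ratio) and raw p value for the factor; the
    Bonferroni family size, when given, is recorded alongside rather than
    applied. On perfect separation, falls back to an L2-penalized fit and
    flags the result (no Wald p is then available).
    """
    cov = [c for c in covariates if c != factor and c in data.columns]
    if data[outcome].nunique() < 2:
        raise ValueError("outcome must have two classes")
    if data[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} is constant")

    def _term(name: str) -> str:
        if pd.api.types.is_numeric_dtype(data[name]):
            return name
        return f"C({name})"

    formula = f"{outcome} ~ {_term(factor)}"
    for c in cov:
        if data[c].nunique() > 1:
            formula += f" + {_term(c)}"
    model = smf.logit(formula, data=data)
    note = ""
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise sm.tools.sm_exceptions.PerfectSeparationError("not converged")
        params, pvalues = fit.params, fit.pvalues
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)
        params = fit.params
        pvalues = pd.Series(np.nan, index=params.index)
        note = "separation: L2-penalized fallback, no Wald p"
    term = next(
        (t for t in params.index if t == factor or t.startswith(f"C({factor})")),
        None,
    )
    if term is None:
        raise ValueError(f"factor term {factor!r} not found in fitted model")
    return TestResult(
        term=term,
        estimate=float(params[term]),
        p_value=float(pvalues[term]),
        n=int(model.exog.shape[0]),
        family_size=family_size,
        note=note,
    )


def asr_regression(
    data: pd.DataFrame,
    response: str,
    asr: str = "asr",
    covariates: tuple[str, ...] = ("sex", "age_dx"),
) -> TestResult:
    """OLS of a burden or attribution on country-level ASR (plus sex, age)."""
    if data[asr].nunique() < 2:
        raise ValueError("ASR is constant (single-country cohort?)")
    formula = f"{response} ~ {asr}"
    for c in covariates:
        if c in data.columns and data[c].nunique() > 1:
            term = c if pd.api.types.is_numeric_dtype(data[c]) else f"C({c})"
            formula += f" + {term}"
    fit = smf.ols(formula, data=data).fit()
    return TestResult(
        term=asr,
        estimate=float(fit.params[asr]),
        p_value=float(fit.pvalues[asr]),
        n=int(fit.nobs),
    )


def country_burden_test(
    burdens: pd.Series, countries: pd.Series, min_per_country: int = 2
) -> TestResult:
    """Kruskal-Wallis comparison of mutation burdens across countries.

    A rank test is used because somatic burdens are heavy-tailed; countries
    with fewer than ``min_per_country`` samples are excluded.
    """
    groups = []
    for _, idx in countries.groupby(countries).groups.items():
        vals = burdens.loc[idx].dropna()
        if len(vals) >= min_per_country:
            groups.append(vals.to_numpy())
    if len(groups) < 2:
        raise ValueError("need at least two countries with enough samples")
    stat, p = stats.kruskal(*groups)
    return TestResult(
        term="country",
        estimate=float(stat),
        p_value=float(p),
        n=int(sum(len(g) for g in groups)),
    )


# ---------------------------------------------------------------------------
# multiple testing and elementary exact tests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (the classic treatment); if every
    difference is zero the test is vacuous and p = 1. Small samples without
    ties use the exact null distribution, larger ones the tie-corrected
    normal approximation.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(term="wilcoxon", estimate=0.0, p_value=1.0, n=0)
    res = stats.wilcoxon(nonzero, method="auto", zero_method="wilcox")
    return TestResult(
        term="wilcoxon",
        estimate=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(nonzero.size),
    )


def fisher_exact_2x2(table) -> TestResult:
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return TestResult(
        term="fisher",
        estimate=float(odds),
        p_value=float(p),
        n=int(np.asarray(table).sum()),
    )


# ---------------------------------------------------------------------------
# clonal / subclonal timing


#: column contract for cluster summary tables
CLUSTER_COLUMNS = ("sample_id", "cluster_id", "ccf", "n_mutations", "top_chrom", "clonal")


def filter_timing_samples(
    clusters: pd.DataFrame,
    purity: pd.Series,
    min_purity: float | None = 0.40,
    max_cluster_ccf: float | None = 1.5,
    drop_chrx_dominant: bool = True,
    min_mutations: int | None = 256,
    max_subclone_ccf: float | None = 0.80,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply the evolutionary-analysis sample and cluster filters.

    In order: sample purity >= 40%; drop artifactual clusters (CCF > 1.5 or
    chromosome X contributing the most mutations); require >= 256 clonal and
    >= 256 subclonal mutations; drop samples with a poorly separated
    subclone (CCF > 0.80); finally require at least one clone and one
    subclone. Every threshold can be disabled by passing ``None`` (or
    ``False`` for the chrX rule). Returns the retained cluster table and a
    per-sample exclusion log naming the first rule that fired.
    """
    excluded: dict[str, str] = {}
    df = clusters.copy()
    samples = list(dict.fromkeys(df["sample_id"]))

    if min_purity is not None:
        for s in samples:
            if purity.get(s, 0.0) < min_purity:
                excluded[s] = "purity"
        df = df[~df["sample_id"].isin(excluded)]

    if max_cluster_ccf is not None:
        df = df[df["ccf"] <= max_cluster_ccf]
    if drop_chrx_dominant:
        df = df[~df["top_chrom"].astype(str).isin(("X", "chrX"))]

    kept = []
    for s, g in df.groupby("sample_id", sort=False):
        clonal_n = int(g.loc[g["clonal"], "n_mutations"].sum())
        sub = g.loc[~g["clonal"]]
        subclonal_n = int(sub["n_mutations"].sum())
        if min_mutations is not None and (
            clonal_n < min_mutations or subclonal_n < min_mutations
        ):
            excluded[s] = "min_mutations"
            continue
        if max_subclone_ccf is not None and (sub["ccf"] > max_subclone_ccf).any():
            excluded[s] = "subclone_separation"
            continue
        if not g["clonal"].any() or sub.empty:
            excluded[s] = "missing_clone_or_subclone"
            continue
        kept.append(s)
    for s in samples:
        if s not in kept and s not in excluded:
            excluded[s] = "missing_clone_or_subclone"
    return df[df["sample_id"].isin(kept)], excluded


def clonal_subclonal_enrichment(
    clonal_cat: CatalogueMatrix,
    subclonal_cat: CatalogueMatrix,
    panel: SignatureMatrix,
    cfg: PenaltyConfig | None = None,
) -> pd.DataFrame:
    """Paired test of per-signature relative activity, clone vs subclone.

    Each sample's clonal and subclonal spectra are attributed against the
    panel independently; activities are normalized by the mutation total of
    the clone or subclone; a two-sided Wilcoxon signed-rank test per
    signature is corrected across signatures by Benjamini-Hochberg.
    """
    cfg = cfg or PenaltyConfig.for_schema(panel.schema.name)
    samples = [s for s in clonal_cat.sample_ids if s in subclonal_cat.sample_ids]
    if len(samples) < 2:
        raise ValueError("need at least two paired samples")
    rel_c = np.zeros((panel.n_signatures, len(samples)))
    rel_s = np.zeros_like(rel_c)
    for i, s in enumerate(samples):
        for mat, rel in ((clonal_cat, rel_c), (subclonal_cat, rel_s)):
            v = mat.column(s)
            total = v.sum()
            if total == 0:
                continue
            e, _ = _point_attribution(v.astype(float), panel, cfg.penalty)
            rel[:, i] = e / total
    rows = []
    for j, sig in enumerate(panel.names):
        if not rel_c[j].any() and not rel_s[j].any():
            continue  # signature never active: nothing to test
        t = wilcoxon_signed_rank(rel_c[j], rel_s[j])
        rows.append(
            {
                "signature": sig,
                "n": len(samples),
                "clonal_mean": rel_c[j].mean(),
                "subclonal_mean": rel_s[j].mean(),
                "statistic": t.estimate,
                "p_value": t.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = bh_adjust(out["p_value"])
    return out


# ---------------------------------------------------------------------------
# driver-spectrum enrichment


def driver_spectrum_enrichment(
    driver_classes: pd.Series,
    exposed: pd.Series,
    target_class: str = "T>A",
) -> tuple[pd.DataFrame, TestResult]:
    """Enrichment of one substitution class among drivers of exposed cases.

    ``driver_classes`` holds the six-class label of each driver SNV and
    ``exposed`` a boolean exposure label per mutation (e.g. carrier status
    of an aristolochic-acid-like signature in the source sample). Returns
    the per-group class proportions and the two-sided Fisher exact test on
    the 2x2 (target class vs other) x (exposed vs unexposed) table.
    """
    exposed = exposed.astype(bool)
    if exposed.all() or (~exposed).all():
        raise ValueError("both exposed and unexposed driver mutations required")
    is_target = driver_classes == target_class
    table = np.array(
        [
            [int((is_target & exposed).sum()), int((~is_target & exposed).sum())],
            [int((is_target & ~exposed).sum()), int((~is_target & ~exposed).sum())],
        ]
    )
    props = pd.DataFrame(
        {
            "group": ["exposed", "unexposed"],
            "n_drivers": table.sum(axis=1),
            f"prop_{target_class}": table[:, 0] / table.sum(axis=1),
        }
    )
    return props, fisher_exact_2x2(table)
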