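"""Template-enrichment testing, junction-profile summaries, and intergroup
SV-frequency comparison.

The enrichment test treats each searched insertion junction of a given size
as a Bernoulli trial whose success probability is the chance of >=1 random
exact match of its query in the 4 kb search space: matches arise at Poisson
rate ``mu = search_space / 4**n_template_bases``, so the trial probability is
``1 - exp(-mu)`` and the p-value is the upper binomial tail at the observed
number of junctions with identified templates.

SV counts per sample are modeled as an overdispersed Poisson (negative
binomial GLM) with the experimental group and batch as covariates and
log(coverage) as an exposure offset of slope 1; the intergroup p-value is the
two-sided Wald test on the group coefficient, with a plain Poisson fallback
when the overdispersed fit fails.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "EnrichmentResult",
    "JunctionProfile",
    "FrequencyComparison",
    "SvFrequencyModel",
    "SvFrequencyResults",
    "enrichment_test",
    "enrichment_by_size",
    "junction_profile",
    "compare_frequency",
]


class UndefinedTestError(ValueError):
    """Raised when a test is requested on an empty stratum."""


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-insertion-size template yield versus the random expectation."""

    insert_size: int
    n_template_bases: int
    n_searched: int
    n_found: int
    search_space: int
    mu: float
    p_trial: float
    p_value: float

    @property
    def expected_found(self) -> float:
        return self.n_searched * self.p_trial


def enrichment_test(
    n_searched: int,
    n_found: int,
    n_template_bases: int,
    search_space: int = 4000,
    insert_size: int = 0,
) -> EnrichmentResult:
    """Upper-tail binomial test of template yield against random matching.

    ``mu = search_space * 4**(-n_template_bases)`` is the expected number of
    random matches per junction; ``p_trial = 1 - exp(-mu)``; the p-value is
    ``P(X >= n_found)`` for X ~ Binomial(n_searched, p_trial).
    """
    if n_searched == 0:
        raise UndefinedTestError("enrichment test undefined with zero searched junctions")
    if n_found > n_searched:
        raise ValueError("n_found cannot exceed n_searched")
    if n_template_bases < 7:
        raise ValueError("queries always comprise at least seven template bases")
    mu = search_space * 4.0 ** (-n_template_bases)
    p_trial = -math.expm1(-mu)
    p_value = float(sps.binom.sf(n_found - 1, n_searched, p_trial))
    return EnrichmentResult(
        insert_size=insert_size,
        n_template_bases=n_template_bases,
        n_searched=n_searched,
        n_found=n_found,
        search_space=search_space,
        mu=mu,
        p_trial=p_trial,
        p_value=min(p_value, 1.0),
    )


def enrichment_by_size(
    insert_sizes: Sequence[int],
    found: Sequence[bool],
    n_template_bases: Sequence[int],
    search_space: int = 4000,
) -> pd.DataFrame:
    """Stratify the enrichment test per insertion size over a cohort of
    searched junctions (one row per size)."""
    df = pd.DataFrame(
        {"insert_size": insert_sizes, "found": found, "ntb": n_template_bases}
    )
    rows = []
    for size, sub in df.groupby("insert_size"):
        r = enrichment_test(
            n_searched=len(sub),
            n_found=int(sub["found"].sum()),
            n_template_bases=int(sub["ntb"].iloc[0]),
            search_space=search_space,
            insert_size=int(size),
        )
        rows.append(r)
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class JunctionProfile:
    """Per-cohort junction summary: mean microhomology of non-insertion
    junctions and the fraction of all junctions with 2–15 bp insertions."""

    n_junctions: int
    mean_mh_no_insertion: float
    frac_insertion_2to15: float
    offset_histogram: pd.Series

    @property
    def empty(self) -> bool:
        return self.n_junctions == 0


def junction_profile(offsets: Sequence[int]) -> JunctionProfile:
    """Summarize junction offsets (microhomology < 0, blunt = 0, insertion > 0)."""
    arr = np.asarray(list(offsets), dtype=int)
    if arr.size == 0:
        return JunctionProfile(0, float("nan"), float("nan"), pd.Series(dtype=int))
    non_ins = arr[arr <= 0]
    mean_mh = float((-non_ins).mean()) if non_ins.size else float("nan")
    frac_ins = float(((arr >= 2) & (arr <= 15)).mean())
    hist = pd.Series(arr).value_counts().sort_index()
    return JunctionProfile(int(arr.size), mean_mh, frac_ins, hist)


@dataclass
class FrequencyComparison:
    """Intergroup SV-rate contrast from the overdispersed count model."""

    group_ref: str
    group_alt: str
    log_rate_ratio: float
    std_err: float
    p_value: float
    model_used: str                  # "negative_binomial" | "poisson_fallback"
    dispersion: float                # NB2 alpha (nan under the Poisson fallback)
    n_samples: dict
    batch_dropped: bool = False
    zero_count_group: bool = False

    @property
    def rate_ratio(self) -> float:
        return math.exp(self.log_rate_ratio)


class SvFrequencyModel:
    """Negative-binomial GLM for per-sample SV counts with coverage exposure.

    Models ``log E[nSvs] = intercept + groupCoef*[group == group_alt]
    + batch effects + log(coverage)`` with NB2 overdispersion estimated by
    maximum likelihood. Batch is encoded as indicator contrasts against the
    alphabetically first batch; a batch perfectly confounded with group is
    dropped with a warning.
    """

    def __init__(
        self,
        counts: Sequence[int],
        coverage: Sequence[float],
        group: Sequence[str],
        batch: Optional[Sequence[str]] = None,
        group_ref: Optional[str] = None,
        group_alt: Optional[str] = None,
    ):
        self.counts = np.asarray(list(counts), dtype=float)
        self.coverage = np.asarray(list(coverage), dtype=float)
        self.group = np.asarray(list(group), dtype=object)
        self.batch = np.asarray(list(batch), dtype=object) if batch is not None else None
        levels = sorted(set(self.group))
        if group_ref is None or group_alt is None:
            if len(levels) != 2:
                raise ValueError("specify group_ref/group_alt for >2 groups")
            group_ref, group_alt = levels
        self.group_ref, self.group_alt = group_ref, group_alt
        mask = (self.group == group_ref) | (self.group == group_alt)
        self.counts = self.counts[mask]
        self.coverage = self.coverage[mask]
        self.group = self.group[mask]
        if self.batch is not None:
            self.batch = self.batch[mask]
        if (self.group == group_ref).sum() == 0 or (self.group == group_alt).sum() == 0:
            raise ValueError("each compared group needs at least one sample")
        if np.any(self.coverage <= 0):
            raise ValueError("coverage must be positive for every sample")
        self.batch_dropped = False
        self._build_design()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        count_col: str = "nSvs",
        coverage_col: str = "coverage",
        group_col: str = "group",
        batch_col: Optional[str] = "batch",
        group_ref: Optional[str] = None,
        group_alt: Optional[str] = None,
    ) -> "SvFrequencyModel":
        batch = df[batch_col] if batch_col and batch_col in df.columns else None
        return cls(
            df[count_col], df[coverage_col], df[group_col], batch,
            group_ref=group_ref, group_alt=group_alt,
        )

    def _build_design(self) -> None:
        n = len(self.counts)
        cols = [np.ones(n), (self.group == self.group_alt).astype(float)]
        names = ["intercept", f"group[{self.group_alt}]"]
        if self.batch is not None:
            levels = sorted(set(self.batch))
            batch_cols, batch_names = [], []
            for lev in levels[1:]:
                batch_cols.append((self.batch == lev).astype(float))
                batch_names.append(f"batch[{lev}]")
            if batch_cols:
                X = np.column_stack(cols + batch_cols)
                if np.linalg.matrix_rank(X) < X.shape[1]:
                    warnings.warn(
                        "batch is confounded with group; dropping the batch term",
                        stacklevel=3,
                    )
                    self.batch_dropped = True
                else:
                    cols += batch_cols
                    names += batch_names
        self.exog = np.column_stack(cols)
        self.exog_names = names

    def fit(self, maxiter: int = 200) -> "SvFrequencyResults":
        """Fit the NB GLM; fall back to a plain Poisson GLM when the
        overdispersed fit fails to converge or implies variance/mean
        indistinguishable from 1."""
        y, X, exposure = self.counts, self.exog, self.coverage
        model_used = "negative_binomial"
        alpha = float("nan")
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                nb = sm.NegativeBinomial(y, X, exposure=exposure)
                nb_res = nb.fit(disp=0, maxiter=maxiter)
                converged = bool(nb_res.mle_retvals.get("converged", False))
                alpha = float(nb_res.params[-1])
                mu = np.exp(X @ nb_res.params[:-1] + np.log(exposure))
                var_over_mean = 1.0 + alpha * float(np.mean(mu))
                ok = (
                    converged
                    and np.all(np.isfinite(nb_res.bse[: X.shape[1]]))
                    and var_over_mean >= 1.0 + 1e-6
                    and alpha < 1e6
                )
                if ok:
                    res = nb_res
            except Exception:
                res = None
            if res is None:
                model_used = "poisson_fallback"
                alpha = float("nan")
                res = sm.Poisson(y, X, exposure=exposure).fit(disp=0, maxiter=maxiter)
        return SvFrequencyResults(self, res, model_used, alpha)


class SvFrequencyResults:
    """Fit results for :class:`SvFrequencyModel` with Wald inference on the
    group coefficient."""

    def __init__(self, model: SvFrequencyModel, res, model_used: str, alpha: float):
        self.model = model
        self._res = res
        self.model_used = model_used
        self.dispersion = alpha
        self.params = np.asarray(res.params[: model.exog.shape[1]])
        self.bse = np.asarray(res.bse[: model.exog.shape[1]])
        self.log_rate_ratio = float(self.params[1])
        self.std_err = float(self.bse[1])
        self.p_value = float(res.pvalues[1])

    @property
    def rate_ratio(self) -> float:
        return math.exp(self.log_rate_ratio)

    def comparison(self) -> FrequencyComparison:
        m = self.model
        zero = any(
            m.counts[m.group == g].sum() == 0 for g in (m.group_ref, m.group_alt)
        )
        return FrequencyComparison(
            group_ref=m.group_ref,
            group_alt=m.group_alt,
            log_rate_ratio=self.log_rate_ratio,
            std_err=self.std_err,
            p_value=self.p_value,
            model_used=self.model_used,
            dispersion=self.dispersion,
            n_samples={
                m.group_ref: int((m.group == m.group_ref).sum()),
                m.group_alt: int((m.group == m.group_alt).sum()),
            },
            batch_dropped=m.batch_dropped,
            zero_count_group=zero,
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "SV frequency comparison (counts ~ group + batch + offset(log coverage))",
            f"  model:         {self.model_used}",
            f"  contrast:      {m.group_alt} vs {m.group_ref}",
            f"  n samples:     {int((m.group == m.group_ref).sum())} ref, "
            f"{int((m.group == m.group_alt).sum())} alt",
            f"  log rate ratio {self.log_rate_ratio:+.4f}  (SE {self.std_err:.4f})",
            f"  rate ratio     {self.rate_ratio:.4f}",
            f"  Wald p-value   {self.p_value:.3e}",
        ]
        if self.model_used == "negative_binomial":
            lines.append(f"  dispersion     alpha = {self.dispersion:.4f}")
        if m.batch_dropped:
            lines.append("  note: batch confounded with group; batch term dropped")
        return "\n".join(lines)


def compare_frequency(
    counts: Sequence[int],
    coverage: Sequence[float],
    group: Sequence[str],
    batch: Optional[Sequence[str]] = None,
    group_ref: Optional[str] = None,
    group_alt: Optional[str] = None,
) -> FrequencyComparison:
    """Functional wrapper: fit the NB frequency model and return the
    intergroup contrast."""
    model = SvFrequencyModel(
        counts, coverage, group, batch, group_ref=group_ref, group_alt=group_alt
    )
    return model.fit().comparison()
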