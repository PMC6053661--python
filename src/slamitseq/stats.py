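"""Beta-binomial inference for cell-type-specific RNA labelling.

The T>C conversion count of a gene in one animal is modelled as a binomial
draw over that animal's sequenced reference-T positions, with a conversion
probability that varies between biological replicates according to a Beta
distribution.  Marginally each replicate's count is therefore beta-binomial
with mean ``mu`` and intra-class correlation (overdispersion) ``rho``:

    alpha = mu * (1 - rho) / rho,   beta = (1 - mu) * (1 - rho) / rho

``rho -> 0`` recovers the plain binomial.  Labelled transcripts are found by
a likelihood-ratio test of group-specific means (Cre+ vs Cre-) against a
common mean, with the dispersion shared across groups and hypotheses, and
Benjamini-Hochberg control of the false discovery rate over genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import betaln, expit, gammaln, logit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaBinParams",
    "FilterReport",
    "GroupTestResult",
    "MannWhitneyResult",
    "adjust_bh",
    "betabin_group_test",
    "betabin_loglik",
    "call_labelled",
    "filter_zero_coverage",
    "groupwise_rate_test",
    "run_labelling_tests",
]

# Below this dispersion the beta-binomial is evaluated through its binomial
# limit; the closed forms agree to ~1e-7 well before the switch.
_RHO_BINOMIAL_LIMIT = 1e-10


@dataclass(frozen=True)
class BetaBinParams:
    """Mean/overdispersion parameterisation of the beta-binomial.

    Parameters
    ----------
    mu:
        Mean conversion probability, in (0, 1).
    rho:
        Intra-class correlation in [0, 1).  ``rho = 0`` is the binomial.
    """

    mu: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")

    @property
    def alpha(self) -> float:
        if self.rho == 0.0:
            raise ValueError("shape parameters are undefined at rho=0")
        return self.mu * (1.0 - self.rho) / self.rho

    @property
    def beta(self) -> float:
        if self.rho == 0.0:
            raise ValueError("shape parameters are undefined at rho=0")
        return (1.0 - self.mu) * (1.0 - self.rho) / self.rho


def _betabin_logpmf(k: np.ndarray, n: np.ndarray, mu: float, rho: float) -> np.ndarray:
    """Log pmf per observation; binomial limit for vanishing rho."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    comb = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    if rho < _RHO_BINOMIAL_LIMIT:
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = comb + k * np.log(mu) + (n - k) * np.log1p(-mu)
        # 0*log(0) at the parameter-space boundary contributes nothing
        lp = np.where((k == 0) & (mu == 0.0), comb, lp)
        lp = np.where((k == n) & (mu == 1.0), comb, lp)
        return lp
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return comb + betaln(k + a, n - k + b) - betaln(a, b)


def betabin_loglik(
    counts: Sequence[tuple[int, int]] | np.ndarray, params: BetaBinParams
) -> float:
    """Total log-likelihood of replicate (k, n) pairs under ``params``.

    Continuous in ``rho`` down to the binomial limit at ``rho = 0``.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("counts must be a sequence of (k, n) pairs")
    k, n = arr[:, 0], arr[:, 1]
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n and n >= 1 for every replicate")
    return float(np.sum(_betabin_logpmf(k, n, params.mu, params.rho)))


class GroupTestResult(NamedTuple):
    """Outcome of the two-group beta-binomial likelihood-ratio test."""

    statistic: float
    p_value: float
    mu_pos: float
    mu_neg: float
    rho_hat: float
    converged: bool


def _clamp(x: np.ndarray | float, lo: float, hi: float):
    return np.minimum(np.maximum(x, lo), hi)


_MU_FLOOR = 1e-12
_RHO_CEIL = 1.0 - 1e-9


def _moment_rho(k: np.ndarray, n: np.ndarray, mu: float) -> float:
    """Method-of-moments start for the intra-class correlation."""
    if mu <= 0.0 or mu >= 1.0 or len(k) < 2:
        return 1e-4
    f = k / n
    v = float(np.var(f, ddof=1))
    # binomial sampling alone contributes mu(1-mu)*mean(1/n)
    v_bin = mu * (1.0 - mu) * float(np.mean(1.0 / n))
    rho = (v - v_bin) / (mu * (1.0 - mu)) if v > v_bin else 1e-4
    return float(_clamp(rho, 1e-6, 0.5))


def _neg_loglik_null(x, k, n):
    mu = expit(x[0])
    rho = expit(x[1])
    return -float(np.sum(_betabin_logpmf(k, n, mu, rho)))


def _neg_loglik_alt(x, kp, np_, kn, nn):
    mu1, mu2, rho = expit(x[0]), expit(x[1]), expit(x[2])
    return -(
        float(np.sum(_betabin_logpmf(kp, np_, mu1, rho)))
        + float(np.sum(_betabin_logpmf(kn, nn, mu2, rho)))
    )


def _binomial_lrt(kp, np_, kn, nn) -> GroupTestResult:
    """Closed-form LRT in the rho=0 (binomial) limit: MLEs are pooled fractions."""
    mu1 = kp.sum() / np_.sum()
    mu2 = kn.sum() / nn.sum()
    mu0 = (kp.sum() + kn.sum()) / (np_.sum() + nn.sum())
    ll1 = np.sum(_betabin_logpmf(kp, np_, mu1, 0.0)) + np.sum(
        _betabin_logpmf(kn, nn, mu2, 0.0)
    )
    ll0 = np.sum(_betabin_logpmf(kp, np_, mu0, 0.0)) + np.sum(
        _betabin_logpmf(kn, nn, mu0, 0.0)
    )
    stat = max(0.0, 2.0 * float(ll1 - ll0))
    p = float(_clamp(sps.chi2.sf(stat, df=1), 1e-300, 1.0))
    return GroupTestResult(stat, p, float(mu1), float(mu2), 0.0, True)


def betabin_group_test(
    pos: Sequence[tuple[int, int]],
    neg: Sequence[tuple[int, int]],
    fixed_rho: float | None = None,
) -> GroupTestResult:
    """Likelihood-ratio test for a group difference in conversion probability.

    H0: both groups share one mean ``mu`` (and a common dispersion ``rho``);
    H1: group-specific means, same shared ``rho``.  Both hypotheses are fitted
    by maximum likelihood on logit-transformed coordinates with a Nelder-Mead
    simplex from method-of-moments starts.  The statistic ``2*(l1 - l0)`` is
    referred to a chi-square with one degree of freedom.

    Parameters
    ----------
    pos, neg:
        Replicate (tc_count, t_coverage) pairs for the Cre+ and Cre- groups.
    fixed_rho:
        If given, the dispersion is held at this value instead of being
        estimated; ``fixed_rho = 0`` reduces the test to a binomial LRT with
        closed-form estimates.
    """
    ap = np.asarray(pos, dtype=float)
    an = np.asarray(neg, dtype=float)
    for name, a in (("pos", ap), ("neg", an)):
        if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
            raise ValueError(f"{name} group needs >= 2 replicate (k, n) pairs")
        if np.any(a[:, 1] < 1) or np.any(a[:, 0] < 0) or np.any(a[:, 0] > a[:, 1]):
            raise ValueError(f"{name} group violates 0 <= k <= n, n >= 1")
    kp, np_ = ap[:, 0], ap[:, 1]
    kn, nn = an[:, 0], an[:, 1]

    # degenerate likelihood surface: nothing converted anywhere
    if kp.sum() == 0 and kn.sum() == 0:
        return GroupTestResult(0.0, 1.0, 0.0, 0.0, 0.0, True)

    if fixed_rho is not None and fixed_rho < _RHO_BINOMIAL_LIMIT:
        return _binomial_lrt(kp, np_, kn, nn)

    mu1_0 = float(_clamp(kp.sum() / np_.sum(), _MU_FLOOR, 1 - _MU_FLOOR))
    mu2_0 = float(_clamp(kn.sum() / nn.sum(), _MU_FLOOR, 1 - _MU_FLOOR))
    mu0_0 = float(
        _clamp((kp.sum() + kn.sum()) / (np_.sum() + nn.sum()), _MU_FLOOR, 1 - _MU_FLOOR)
    )

    opts = {"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8}
    _XMU = (-34.5, 34.5)  # logit(mu), keeps mu away from exact 0/1
    _XRHO = (logit(1e-8), logit(_RHO_CEIL))

    if fixed_rho is not None:
        rho = float(_clamp(fixed_rho, _RHO_BINOMIAL_LIMIT, _RHO_CEIL))
        r0 = optimize.minimize(
            lambda x: _neg_loglik_null(
                np.array([x[0], logit(rho)]), np.r_[kp, kn], np.r_[np_, nn]
            ),
            np.array([logit(mu0_0)]),
            method="L-BFGS-B",
            bounds=[_XMU],
            options=opts,
        )
        r1 = optimize.minimize(
            lambda x: _neg_loglik_alt(np.array([x[0], x[1], logit(rho)]), kp, np_, kn, nn),
            np.array([logit(mu1_0), logit(mu2_0)]),
            method="L-BFGS-B",
            bounds=[_XMU, _XMU],
            options=opts,
        )
        if not (r0.success and r1.success):
            warnings.warn(
                "beta-binomial optimiser did not converge; reporting p=1 for this gene",
                RuntimeWarning,
                stacklevel=2,
            )
            return GroupTestResult(
                0.0, 1.0, float(expit(r1.x[0])), float(expit(r1.x[1])), rho, False
            )
        mu_pos, mu_neg = float(expit(r1.x[0])), float(expit(r1.x[1]))
        rho_hat = float(fixed_rho)
        ll0, ll1 = -float(r0.fun), -float(r1.fun)
    else:
        # One dispersion for everything: rho is estimated by maximum
        # likelihood under the full (group-specific means) model and then
        # held fixed for the null fit, so that a genuine group difference is
        # not re-absorbed as spurious replicate overdispersion.  The fit is a
        # bounded quasi-Newton search on logit coordinates from a
        # method-of-moments start, compared against the closed-form rho=0
        # boundary fit: the MLE sits on the boundary whenever replicates are
        # no more variable than binomial sampling allows.
        k_all, n_all = np.r_[kp, kn], np.r_[np_, nn]
        rho0 = _moment_rho(k_all, n_all, mu0_0)
        r1 = optimize.minimize(
            _neg_loglik_alt,
            np.array([logit(mu1_0), logit(mu2_0), logit(rho0)]),
            args=(kp, np_, kn, nn),
            method="L-BFGS-B",
            bounds=[_XMU, _XMU, _XRHO],
            options=opts,
        )
        ll1_bin = float(
            np.sum(_betabin_logpmf(kp, np_, mu1_0, 0.0))
            + np.sum(_betabin_logpmf(kn, nn, mu2_0, 0.0))
        )
        if not r1.success:
            # quasi-Newton line searches can stall on flat dispersion
            # profiles; polish with a simplex restart before giving up
            r1b = optimize.minimize(
                _neg_loglik_alt,
                r1.x,
                args=(kp, np_, kn, nn),
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000, "maxfev": 4000},
            )
            if r1b.fun <= r1.fun:
                r1 = r1b
        if not r1.success and -r1.fun > ll1_bin:
            # only fatal if the interior optimum actually mattered
            warnings.warn(
                "beta-binomial optimiser did not converge; reporting p=1 for this gene",
                RuntimeWarning,
                stacklevel=2,
            )
            return GroupTestResult(
                0.0,
                1.0,
                float(expit(r1.x[0])),
                float(expit(r1.x[1])),
                float(expit(r1.x[2])),
                False,
            )
        if -float(r1.fun) >= ll1_bin:
            ll1 = -float(r1.fun)
            mu_pos, mu_neg = float(expit(r1.x[0])), float(expit(r1.x[1]))
            rho_hat = float(expit(r1.x[2]))
            if rho_hat <= 1.01e-8:  # pinned to the lower bound: boundary case
                rho_hat = 0.0
        else:
            ll1 = ll1_bin
            mu_pos, mu_neg, rho_hat = mu1_0, mu2_0, 0.0

        if rho_hat == 0.0:
            ll0 = float(np.sum(_betabin_logpmf(k_all, n_all, mu0_0, 0.0)))
        else:
            r0 = optimize.minimize(
                lambda x: _neg_loglik_null(
                    np.array([x[0], logit(rho_hat)]), k_all, n_all
                ),
                np.array([logit(mu0_0)]),
                method="L-BFGS-B",
                bounds=[_XMU],
                options=opts,
            )
            if not r0.success:
                warnings.warn(
                    "beta-binomial optimiser did not converge; reporting p=1 "
                    "for this gene",
                    RuntimeWarning,
                    stacklevel=2,
                )
                return GroupTestResult(0.0, 1.0, mu_pos, mu_neg, rho_hat, False)
            ll0 = -float(r0.fun)

    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(_clamp(sps.chi2.sf(stat, df=1), 1e-300, 1.0))
    return GroupTestResult(stat, p, mu_pos, mu_neg, rho_hat, True)


@dataclass
class FilterReport:
    """Book-keeping for the zero-coverage pre-filter."""

    genes_in: int
    genes_removed: int
    removed_genes: list[str] = field(default_factory=list)

    @property
    def genes_tested(self) -> int:
        return self.genes_in - self.genes_removed

    def to_dict(self) -> dict:
        return {
            "genes_in": self.genes_in,
            "genes_removed": self.genes_removed,
            "genes_tested": self.genes_tested,
            "removed_genes": sorted(self.removed_genes),
        }


def filter_zero_coverage(
    table: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop genes with zero T coverage in any sample of the design.

    ``table`` is the long counts table (gene, sample, t_coverage, tc_count);
    ``sheet`` the sample sheet whose ``sample_id`` column defines the samples
    every retained gene must cover with t_coverage >= 1.
    """
    samples = list(sheet["sample_id"])
    missing = set(samples) - set(table["sample"].unique())
    if missing:
        raise ValueError(f"counts table lacks samples from the sheet: {sorted(missing)}")
    sub = table[table["sample"].isin(samples)]
    cov = sub.pivot_table(
        index="gene", columns="sample", values="t_coverage", fill_value=0
    ).reindex(columns=samples, fill_value=0)
    ok = (cov >= 1).all(axis=1)
    keep = set(cov.index[ok])
    removed = sorted(set(cov.index) - keep)
    out = table[table["gene"].isin(keep)].copy()
    report = FilterReport(
        genes_in=cov.shape[0], genes_removed=len(removed), removed_genes=removed
    )
    return out, report


def adjust_bh(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _test_one_gene(pos, neg, fixed_rho=None) -> GroupTestResult:
    return betabin_group_test(pos, neg, fixed_rho=fixed_rho)


def run_labelling_tests(
    table: pd.DataFrame,
    sheet: pd.DataFrame,
    fixed_rho: float | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the per-gene group test over a counts table.

    Applies the zero-coverage filter, then the beta-binomial LRT per gene.
    Returns the per-gene results (without multiplicity adjustment; see
    :func:`call_labelled`) and the filter report.
    """
    filtered, report = filter_zero_coverage(table, sheet)
    if filtered.empty:
        raise ValueError("no genes left after the zero-coverage filter")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    pos_samples = [s for s, g in groups.items() if g == "cre_pos"]
    neg_samples = [s for s, g in groups.items() if g == "cre_neg"]
    if len(pos_samples) < 2 or len(neg_samples) < 2:
        raise ValueError("the replicate test needs >= 2 samples per group")

    rows = []
    for gene, sub in filtered.groupby("gene", sort=True):
        by_sample = sub.set_index("sample")
        pos = [
            (int(by_sample.loc[s, "tc_count"]), int(by_sample.loc[s, "t_coverage"]))
            for s in pos_samples
        ]
        neg = [
            (int(by_sample.loc[s, "tc_count"]), int(by_sample.loc[s, "t_coverage"]))
            for s in neg_samples
        ]
        res = _test_one_gene(pos, neg, fixed_rho=fixed_rho)
        rows.append(
            {
                "gene": gene,
                "mu_pos": res.mu_pos,
                "mu_neg": res.mu_neg,
                "rho_hat": res.rho_hat,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows), report


def call_labelled(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg adjust and call labelled genes at the given FDR.

    A gene is labelled when its q-value clears the threshold AND its fitted
    Cre+ mean exceeds the Cre- mean (the test itself is two-sided; the
    direction filter keeps only enrichment in the labelled genotype).
    Output is sorted by p-value ascending.
    """
    out = results.copy()
    out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    out["direction"] = np.sign(out["mu_pos"] - out["mu_neg"]).astype(int)
    out["labelled"] = (out["q_value"] < fdr) & (out["mu_pos"] > out["mu_neg"])
    return out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)


class MannWhitneyResult(NamedTuple):
    u_statistic: float
    p_value: float
    method: str


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> MannWhitneyResult:
    """Two-sided Mann-Whitney by full enumeration of group assignments.

    Midranks handle ties; the p-value is the probability, over all
    C(n1+n2, n1) relabellings, of a U at least as far from its mean as the
    observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(x), len(y)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = 0
    hits = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return MannWhitneyResult(u_obs, hits / total, "exact")


def groupwise_rate_test(
    rates_pos: Sequence[float], rates_neg: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of per-gene conversion rates.

    Exact enumeration (tie-aware, via midranks) when both groups have at
    most 8 values; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(rates_pos, dtype=float)
    y = np.asarray(rates_neg, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        u = x.size * y.size / 2.0
        return MannWhitneyResult(u, 1.0, "degenerate")
    if x.size <= 8 and y.size <= 8:
        return _exact_mannwhitney(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")
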