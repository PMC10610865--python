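"""Hill dose-response analysis for two-electrode voltage-clamp data.

Model
-----
Peak currents from each oocyte are normalized to that oocyte's control
response, giving a fraction Y of remaining current per inhibitor
concentration.  The decreasing three-parameter Hill curve

    Y(c) = Bottom + (1 - Bottom) / (1 + 10**((X - LogIC50) * nH)),
    X = log10(c in nM)

is fitted per replicate with Top fixed at 1 (the control defines the
scale), Bottom free in [0, 1] (the residual current at saturating
inhibitor) and nH > 0 (the slope magnitude; a decreasing curve can be
written with either sign convention, magnitudes are reported).
Zero-concentration points serve normalization QC and are excluded from
the fit.  Group parameters are summarized as mean +/- SEM over
per-replicate fits; construct-vs-reference comparison uses one-way ANOVA
and Dunnett's many-to-one test with Monte-Carlo critical values, with
IC50 compared on the LogIC50 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

_DEGENERATE_SPAN = 0.05  # minimal observed response span for a meaningful fit

PARAM_NAMES = ("logic50", "bottom", "nh")


@dataclass(frozen=True)
class HillParams:
    """Hill curve parameters: IC50 in nM, Bottom fraction, slope magnitude."""

    ic50_nm: float
    bottom: float
    nh: float

    def __post_init__(self):
        if not self.ic50_nm > 0:
            raise ValueError("IC50 must be positive")
        if not 0.0 <= self.bottom <= 1.0:
            raise ValueError("Bottom must lie in [0, 1]")
        if not self.nh > 0:
            raise ValueError("nH is stored as a positive magnitude")

    @property
    def logic50(self) -> float:
        return float(np.log10(self.ic50_nm))


def hill_predict(params: HillParams, concentration_nm) -> np.ndarray | float:
    """Predicted current fraction at the given concentration(s) in nM.

    Zero concentration returns 1 (the control level, by continuity of the
    decreasing curve as c -> 0).
    """
    c = np.asarray(concentration_nm, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    y = np.ones_like(c)
    nz = c > 0
    x = np.log10(c[nz])
    y[nz] = params.bottom + (1.0 - params.bottom) / (
        1.0 + 10.0 ** ((x - params.logic50) * params.nh)
    )
    return float(y[0]) if scalar else y


def normalize_currents(peak_currents, control_current) -> np.ndarray:
    """Normalize signed peak current amplitudes to the control response.

    The control trace self-normalizes to 1; a zero control is rejected.
    """
    control = float(control_current)
    if control == 0.0:
        raise ValueError("control current must be non-zero")
    return np.asarray(peak_currents, dtype=float) / control


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class HillCurveModel:
    """Three-parameter Hill model for one replicate's dose-response curve.

    Parameters
    ----------
    concentration_nm, fraction
        Measured points.  Zero-concentration points are kept for QC but
        excluded from fitting; at least four distinct non-zero
        concentrations are required.
    """

    def __init__(self, concentration_nm, fraction):
        c = np.asarray(concentration_nm, dtype=float)
        y = np.asarray(fraction, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concentration and fraction must be 1-D and aligned")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(y)):
            raise ValueError("fractions must be finite")
        self.concentration_nm = c
        self.fraction = y
        nz = c > 0
        if len(np.unique(c[nz])) < 4:
            raise ValueError(
                "need at least four distinct non-zero concentrations to fit"
            )
        self.x = np.log10(c[nz])
        self.y = y[nz]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       concentration_col: str = "concentration_nM",
                       fraction_col: str = "fraction") -> "HillCurveModel":
        return cls(df[concentration_col].to_numpy(), df[fraction_col].to_numpy())

    def fit(self, multistart: bool = True) -> "HillCurveResults":
        """Least-squares fit with multi-start initialization (lmfit).

        Starts span the observed concentration range (LogIC50) and slopes
        from shallow to steep; the best run by chi-square wins.  A flat
        curve (response span below 0.05) is flagged degenerate rather than
        fitted silently.
        """
        import lmfit

        x, y = self.x, self.y
        degenerate = float(np.ptp(y)) < _DEGENERATE_SPAN

        def _curve(x, logic50, bottom, nh):
            return bottom + (1.0 - bottom) / (1.0 + 10.0 ** ((x - logic50) * nh))

        model = lmfit.Model(_curve)
        lo, hi = float(x.min()), float(x.max())
        l0_starts = [np.quantile(x, q) for q in (0.25, 0.5, 0.75)]
        nh_starts = [0.8, 1.6, 3.2]
        if not multistart:
            l0_starts, nh_starts = l0_starts[1:2], nh_starts[1:2]
        best = None
        for l0 in l0_starts:
            for nh0 in nh_starts:
                p = model.make_params(
                    logic50=dict(value=float(l0), min=lo - 2.0, max=hi + 2.0),
                    bottom=dict(value=float(np.clip(y.min(), 0.0, 1.0)),
                                min=0.0, max=1.0),
                    nh=dict(value=nh0, min=0.05, max=10.0),
                )
                try:
                    out = model.fit(y, p, x=x)
                except Exception:
                    continue
                if best is None or out.chisqr < best.chisqr:
                    best = out
        if best is None:
            return HillCurveResults(self, params=None, bse={}, sse=np.nan,
                                    converged=False, degenerate=degenerate)
        params = HillParams(
            ic50_nm=float(10.0 ** best.params["logic50"].value),
            bottom=float(best.params["bottom"].value),
            nh=float(best.params["nh"].value),
        )
        bse = {
            name: (float(best.params[name].stderr)
                   if best.params[name].stderr is not None else np.nan)
            for name in PARAM_NAMES
        }
        converged = bool(best.success) and not degenerate
        return HillCurveResults(self, params=params, bse=bse,
                                sse=float(best.chisqr), converged=converged,
                                degenerate=degenerate)


@dataclass
class HillCurveResults:
    """Fit results for one dose-response curve.

    ``params`` holds the point estimates, ``bse`` the asymptotic standard
    errors on (logic50, bottom, nh) where the covariance was estimable,
    ``converged``/``degenerate`` report the fit status honestly.
    """

    model: HillCurveModel
    params: HillParams | None
    bse: dict[str, float]
    sse: float
    converged: bool
    degenerate: bool = False

    @property
    def nobs(self) -> int:
        return len(self.model.y)

    def predict(self, concentration_nm) -> np.ndarray | float:
        if self.params is None:
            raise RuntimeError("fit did not produce parameters")
        return hill_predict(self.params, concentration_nm)

    def summary(self) -> str:
        lines = ["Hill dose-response fit",
                 f"  n points (non-zero conc): {self.nobs}",
                 f"  converged: {self.converged}   degenerate: {self.degenerate}"]
        if self.params is not None:
            se = self.bse
            lines += [
                f"  IC50    = {self.params.ic50_nm:10.4g} nM"
                f"   (LogIC50 {self.params.logic50:.4f}"
                f" +/- {se.get('logic50', np.nan):.4f})",
                f"  Bottom  = {self.params.bottom:10.4f}"
                f"   +/- {se.get('bottom', np.nan):.4f}",
                f"  nH      = {self.params.nh:10.4f}"
                f"   +/- {se.get('nh', np.nan):.4f}",
                f"  SSE     = {self.sse:10.4g}",
            ]
        return "\n".join(lines)


def fit_hill(data: pd.DataFrame,
             replicate_col: str = "replicate_id",
             concentration_col: str = "concentration_nM",
             fraction_col: str = "fraction",
             multistart: bool = True) -> "ReplicateFits":
    """Fit every replicate curve in a tidy dataset.

    ``data`` has one row per (replicate, concentration) measurement.
    Returns a :class:`ReplicateFits` with per-replicate results and a
    mean +/- SEM group summary.
    """
    results: dict = {}
    for rep, sub in data.groupby(replicate_col, sort=True):
        model = HillCurveModel.from_dataframe(
            sub, concentration_col=concentration_col, fraction_col=fraction_col
        )
        results[rep] = model.fit(multistart=multistart)
    return ReplicateFits(results)


def fit_pooled(data: pd.DataFrame,
               concentration_col: str = "concentration_nM",
               fraction_col: str = "fraction") -> HillCurveResults:
    """Single fit to the pooled points of all replicates (non-default mode)."""
    model = HillCurveModel.from_dataframe(
        data, concentration_col=concentration_col, fraction_col=fraction_col
    )
    return model.fit()


@dataclass
class ReplicateFits:
    """Per-replicate Hill fits for one construct."""

    results: dict

    def param_table(self) -> pd.DataFrame:
        rows = []
        for rep, res in self.results.items():
            if res.params is None:
                continue
            rows.append({
                "replicate": rep,
                "ic50_nm": res.params.ic50_nm,
                "logic50": res.params.logic50,
                "bottom": res.params.bottom,
                "nh": res.params.nh,
                "converged": res.converged,
            })
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Group summary: mean +/- SEM of IC50, Bottom and nH over replicates."""
        tab = self.param_table()
        out = {}
        for col in ("ic50_nm", "logic50", "bottom", "nh"):
            vals = tab[col].to_numpy()
            out[col] = {
                "mean": float(np.mean(vals)),
                "sem": float(stats.sem(vals)) if len(vals) > 1 else np.nan,
                "n": len(vals),
            }
        return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# group comparison: one-way ANOVA + Monte-Carlo Dunnett
# ---------------------------------------------------------------------------

_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(p: float) -> str:
    for cut, label in _TIERS:
        if p < cut:
            return label
    return "n.s."


@lru_cache(maxsize=32)
def _dunnett_null_max_abs_t(sizes: tuple[int, ...], n_draws: int,
                            seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of max_j |T_j| for many-to-one contrasts.

    ``sizes`` = (n_ref, n_1, ..., n_k).  Group means are simulated as
    independent normals with variance 1/n_i, the pooled variance as a
    scaled chi-square with N - (k+1) degrees of freedom; T_j is the usual
    Dunnett contrast statistic.  The distribution depends only on the
    group sizes, so it is cached and shared across datasets.
    """
    rng = np.random.default_rng(seed)
    n_ref, rest = sizes[0], sizes[1:]
    df = sum(sizes) - len(sizes)
    means = rng.standard_normal((n_draws, len(sizes))) / np.sqrt(sizes)
    s2 = rng.chisquare(df, size=n_draws) / df
    denom = np.sqrt(s2[:, None] * (1.0 / np.asarray(rest) + 1.0 / n_ref))
    t = (means[:, 1:] - means[:, :1]) / denom
    return np.sort(np.abs(t).max(axis=1))


def dunnett_pvalues(groups: dict[str, np.ndarray], reference: str,
                    seed: int = 0, n_draws: int = 50_000) -> pd.DataFrame:
    """Raw and Dunnett-adjusted two-sided p-values vs the reference group.

    The adjusted p-value of comparison j is the null probability that the
    largest |T| across all comparisons exceeds the observed |t_j|,
    estimated from ``n_draws`` Monte-Carlo draws (seeded).  Monte-Carlo
    noise is clamped to the exact bounds raw p <= adjusted p <= Bonferroni.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} missing")
    others = [g for g in groups if g != reference]
    if not others:
        raise ValueError("need at least one non-reference group")
    ref = np.asarray(groups[reference], dtype=float)
    sizes = (len(ref),) + tuple(len(groups[g]) for g in others)
    if min(sizes) < 3:
        raise ValueError("each group needs at least three replicates")
    k = len(others)
    n_total = sum(sizes)
    df = n_total - (k + 1)
    pooled = np.concatenate([ref - ref.mean()]
                            + [np.asarray(groups[g]) - np.mean(groups[g])
                               for g in others])
    mse = float(np.sum(pooled ** 2) / df)
    null = _dunnett_null_max_abs_t(sizes, n_draws, seed)
    rows = []
    for g, n_g in zip(others, sizes[1:]):
        vals = np.asarray(groups[g], dtype=float)
        se = np.sqrt(mse * (1.0 / n_g + 1.0 / len(ref)))
        t_obs = (vals.mean() - ref.mean()) / se
        raw = float(2.0 * stats.t.sf(abs(t_obs), df))
        adj = float(np.mean(null >= abs(t_obs)))
        adj = min(max(adj, raw), min(k * raw, 1.0))
        rows.append({"group": g, "diff": float(vals.mean() - ref.mean()),
                     "t": float(t_obs), "raw_p": raw, "adj_p": adj,
                     "tier": significance_tier(adj)})
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """ANOVA and Dunnett comparison of fitted parameters across constructs."""

    anova: pd.DataFrame        # parameter, F, p
    comparisons: pd.DataFrame  # parameter, group, diff, raw_p, adj_p, tier
    reference: str

    def summary(self) -> str:
        lines = [f"Parameter comparison vs {self.reference}", "", "ANOVA:"]
        lines.append(self.anova.to_string(index=False))
        lines += ["", "Dunnett many-to-one:"]
        lines.append(self.comparisons.to_string(index=False))
        return "\n".join(lines)


def compare_params(group_fits: dict[str, "ReplicateFits | pd.DataFrame"],
                   reference: str = "WT", seed: int = 0,
                   n_draws: int = 50_000) -> ComparisonResult:
    """Compare fitted Hill parameters of every construct to a reference.

    One-way ANOVA and Monte-Carlo Dunnett per parameter; IC50 is compared
    on the LogIC50 scale (its sampling distribution is far closer to
    normal there), Bottom and nH on their natural scales.
    """
    tables = {
        name: (fits.param_table() if isinstance(fits, ReplicateFits) else fits)
        for name, fits in group_fits.items()
    }
    anova_rows, cmp_rows = [], []
    for param in PARAM_NAMES:
        groups = {name: tab[param].to_numpy(dtype=float)
                  for name, tab in tables.items()}
        f_stat, p = stats.f_oneway(*groups.values())
        anova_rows.append({"parameter": param, "F": float(f_stat),
                           "p": float(p)})
        dn = dunnett_pvalues(groups, reference=reference, seed=seed,
                             n_draws=n_draws)
        dn.insert(0, "parameter", param)
        cmp_rows.append(dn)
    return ComparisonResult(
        anova=pd.DataFrame(anova_rows),
        comparisons=pd.concat(cmp_rows, ignore_index=True),
        reference=reference,
    )
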