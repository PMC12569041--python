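"""Concentration-response, ligand-bias and radioligand-binding analysis.

The module follows a model/results idiom: a model object is built from data
(``from_dataframe`` constructors accept the CSV schemas of :mod:`korbias.io`)
and ``fit()`` returns a results object carrying estimates, uncertainties and
a ``summary()`` table.

Models
------
* :class:`FourParamLogistic` — the four-parameter logistic (4PL)
  concentration-response curve
  ``y = Bottom + (Top - Bottom) / (1 + 10**((log10 EC50 - log10 c) * h))``
  with the Hill slope constrained to |h| <= 2, as used for NanoBiT
  G-protein-dissociation and beta-arrestin-recruitment assays.
* :class:`SaturationBinding` — one-site specific binding
  ``B = Bmax * L / (Kd + L)`` on specific counts (total minus replicate-
  matched nonspecific).
* :class:`CompetitionBinding` — sigmoid in log(inhibitor) yielding IC50,
  converted to Ki by the Cheng-Prusoff equation ``Ki = IC50 / (1 + L/Kd)``.

Derived quantities
------------------
``relative_activity`` normalizes Span, pEC50 and Span/EC50 of a test
construct to a wild-type reference fitted in parallel (Emax, delta-pEC50,
RAi); ``bias_factor`` computes the ligand-bias statistic
``ddLog(Emax/EC50)`` between two pathways with a two-sided one-sample
t-test against zero. Logs are base 10 and EC50s are molar throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "four_pl",
    "FourParamLogistic",
    "FourPLResults",
    "normalize_kinetic",
    "RelativeActivity",
    "relative_activity",
    "BiasResult",
    "bias_factor",
    "significance_stars",
    "SaturationBinding",
    "SaturationResults",
    "CompetitionBinding",
    "CompetitionResults",
    "cheng_prusoff",
]


def four_pl(
    conc: np.ndarray, bottom: float, top: float, pec50: float, hill: float
) -> np.ndarray:
    """4PL response at molar concentrations ``conc``."""
    conc = np.asarray(conc, dtype=float)
    logc = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((-pec50 - logc) * hill))


def _logistic_least_squares(
    logc: np.ndarray,
    y: np.ndarray,
    hill_bound: float,
    logec50_starts: Sequence[float],
    hill_signs: Sequence[float] = (1.0, -1.0),
) -> tuple[np.ndarray, float, bool, np.ndarray | None]:
    """Bounded least-squares fit of the 4PL in (bottom, top, logec50, hill).

    Multi-start in log-EC50 (and the given Hill signs); returns the best
    (params, rss, converged, jacobian).
    """
    lo = np.array([-np.inf, -np.inf, logc.min() - 3.0, -hill_bound])
    hi = np.array([np.inf, np.inf, logc.max() + 3.0, hill_bound])

    def resid(p):
        b, t, le, h = p
        return b + (t - b) / (1.0 + 10.0 ** ((le - logc) * h)) - y

    ymin, ymax = float(y.min()), float(y.max())
    best = None
    for le0 in logec50_starts:
        for h0 in hill_signs:
            p0 = np.array(
                [ymin, ymax, np.clip(le0, lo[2] + 1e-9, hi[2] - 1e-9),
                 h0 * min(1.0, hill_bound)]
            )
            try:
                sol = optimize.least_squares(
                    resid, p0, bounds=(lo, hi), method="trf", xtol=1e-12,
                    ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[1] - 1e-15:
                best = (sol.x, rss, bool(sol.success), sol.jac)
    if best is None:
        return np.array([ymin, ymax, logc.mean(), 1.0]), float("inf"), False, None
    return best


def _cov_from_jac(jac: np.ndarray | None, rss: float, n: int, k: int):
    if jac is None or n <= k:
        return None
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (rss / (n - k))
    except np.linalg.LinAlgError:
        return None
    return cov


@dataclass
class FourPLResults:
    """Fitted 4PL parameters with diagnostics."""

    bottom: float
    top: float
    pec50: float
    hill: float
    rss: float
    n_obs: int
    converged: bool
    flat: bool
    cov: np.ndarray | None = None

    @property
    def span(self) -> float:
        return self.top - self.bottom

    @property
    def ec50(self) -> float:
        return 10.0 ** (-self.pec50)

    @property
    def log_span_over_ec50(self) -> float:
        """log10(Span/EC50), the per-curve transduction quantity."""
        if self.span <= 0:
            raise ValueError("log10(Span/EC50) undefined for non-positive Span")
        return math.log10(self.span) + self.pec50

    def bse(self) -> np.ndarray | None:
        """Asymptotic standard errors for (bottom, top, pEC50, hill)."""
        if self.cov is None:
            return None
        se = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        # internal parameterization uses logEC50 = -pEC50: same se
        return se

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return four_pl(conc, self.bottom, self.top, self.pec50, self.hill)

    def plot(self, conc=None, response=None, ax=None):
        """Plot the fitted curve (and optionally the data) on log-x axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo = -self.pec50 - 3 if conc is None else np.log10(np.min(conc)) - 0.5
        hi = -self.pec50 + 3 if conc is None else np.log10(np.max(conc)) + 0.5
        grid = np.logspace(lo, hi, 200)
        ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
        if conc is not None and response is not None:
            ax.semilogx(conc, response, "o", label="data")
        ax.set_xlabel("concentration (M)")
        ax.set_ylabel("response")
        ax.legend()
        return ax

    def summary(self) -> str:
        se = self.bse()
        lines = [
            "Four-parameter logistic fit",
            f"  n_obs      : {self.n_obs}",
            f"  converged  : {self.converged}" + ("  (flat data)" if self.flat else ""),
            f"  Bottom     : {self.bottom:.6g}",
            f"  Top        : {self.top:.6g}",
            f"  Span       : {self.span:.6g}",
            f"  pEC50      : {self.pec50:.6g}"
            + (f" +/- {se[2]:.3g}" if se is not None else ""),
            f"  EC50 (M)   : {self.ec50:.6g}",
            f"  HillSlope  : {self.hill:.6g} (|h| <= 2)",
            f"  RSS        : {self.rss:.6g}",
        ]
        return "\n".join(lines)


class FourParamLogistic:
    """4PL concentration-response model for one curve.

    Parameters
    ----------
    concentration : array of molar concentrations (> 0)
    response : array of normalized responses, same length
    """

    def __init__(self, concentration, response):
        conc = np.asarray(concentration, dtype=float)
        resp = np.asarray(response, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValueError("concentration and response must be 1-D and matched")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (molar)")
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 distinct concentrations for a 4PL fit")
        self.concentration = conc
        self.response = resp

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conc_col: str = "conc_M",
        response_col: str = "response",
    ) -> "FourParamLogistic":
        return cls(df[conc_col].to_numpy(), df[response_col].to_numpy())

    def fit(self, hill_bound: float = 2.0, n_starts: int = 5) -> FourPLResults:
        """Bounded least-squares fit with multi-start in log-EC50.

        Flat data (response range indistinguishable from noise-free zero
        span) is flagged rather than failed.
        """
        logc = np.log10(self.concentration)
        y = self.response
        yr = float(y.max() - y.min())
        scale = max(abs(y).max(), 1.0)
        if yr <= 1e-12 * scale:
            return FourPLResults(
                bottom=float(y.mean()), top=float(y.mean()), pec50=-logc.mean(),
                hill=1.0, rss=float(np.sum((y - y.mean()) ** 2)),
                n_obs=len(y), converged=True, flat=True,
            )
        if n_starts == 1:
            # data-driven single start: log-EC50 at the half-height crossing,
            # Hill sign from the response/log-concentration correlation
            mid = 0.5 * (y.min() + y.max())
            le0 = float(logc[np.argmin(np.abs(y - mid))])
            slope = float(np.corrcoef(logc, y)[0, 1])
            signs = (1.0,) if slope >= 0 else (-1.0,)
            params, rss, ok, jac = _logistic_least_squares(
                logc, y, hill_bound, [le0], signs
            )
        else:
            starts = list(np.linspace(logc.min(), logc.max(), n_starts))
            params, rss, ok, jac = _logistic_least_squares(logc, y, hill_bound, starts)
        b, t, le, h = params
        # the 4PL is invariant under (b, t, h) -> (t, b, -h); canonicalize
        # to Top > Bottom so the Hill sign alone carries curve direction
        if t < b:
            b, t, h = t, b, -h
            if jac is not None:
                jac = jac[:, [1, 0, 2, 3]]
        cov = _cov_from_jac(jac, rss, len(y), 4)
        return FourPLResults(
            bottom=float(b), top=float(t), pec50=float(-le), hill=float(h),
            rss=rss, n_obs=len(y), converged=ok, flat=False, cov=cov,
        )


def fit_4pl(df: pd.DataFrame, hill_bound: float = 2.0) -> FourPLResults:
    """Convenience wrapper: fit one curve from a dose_response dataframe."""
    return FourParamLogistic.from_dataframe(df).fit(hill_bound=hill_bound)


# ---------------------------------------------------------------------------
# kinetic normalization


def normalize_kinetic(
    df: pd.DataFrame,
    baseline_window: tuple[float, float] = (-np.inf, 0.0),
    response_window: tuple[float, float] = (300.0, 600.0),
    vehicle_ligand: str = "vehicle",
    pathway: str = "Gprotein",
) -> pd.DataFrame:
    """Reduce kinetic luminescence reads to a dose_response dataset.

    Per well, counts inside the response window (default 5-10 min after
    addition) are averaged and divided by the baseline counts; the fold
    change is then divided by the fold change of the vehicle wells of the
    same construct and replicate.
    """
    required = {"well", "time_s", "counts", "construct", "ligand", "conc_M", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kinetic table missing columns {sorted(missing)}")

    folds = []
    for (well, construct, ligand, conc, rep), g in df.groupby(
        ["well", "construct", "ligand", "conc_M", "replicate"], sort=False
    ):
        t = g["time_s"].to_numpy(dtype=float)
        c = g["counts"].to_numpy(dtype=float)
        base = c[(t >= baseline_window[0]) & (t <= baseline_window[1])]
        resp = c[(t >= response_window[0]) & (t <= response_window[1])]
        if base.size == 0:
            raise ValueError(f"well {well!r}: no baseline reads")
        if resp.size == 0:
            raise ValueError(f"well {well!r}: no reads in response window")
        if abs(base.mean()) < 1e-30:
            raise ValueError(f"well {well!r}: zero baseline counts")
        folds.append(
            {"well": well, "construct": construct, "ligand": ligand,
             "conc_M": conc, "replicate": rep, "fold": resp.mean() / base.mean()}
        )
    fold_df = pd.DataFrame(folds)

    vehicle = fold_df[fold_df["ligand"] == vehicle_ligand]
    if vehicle.empty:
        raise ValueError(f"no vehicle wells (ligand == {vehicle_ligand!r}) found")
    veh_fold = vehicle.groupby(["construct", "replicate"])["fold"].mean()

    rows = []
    for _, r in fold_df[fold_df["ligand"] != vehicle_ligand].iterrows():
        key = (r["construct"], r["replicate"])
        if key not in veh_fold.index:
            raise ValueError(
                f"no vehicle wells for construct/replicate {key}"
            )
        rows.append(
            {"ligand": r["ligand"], "pathway": pathway,
             "construct": r["construct"], "conc_M": r["conc_M"],
             "response": r["fold"] / veh_fold.loc[key],
             "replicate": r["replicate"]}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# WT-normalized activity and ligand bias


@dataclass
class RelativeActivity:
    """Per-replicate test-vs-reference activity parameters and their means."""

    emax: np.ndarray          # Span_test / Span_ref
    delta_pec50: np.ndarray   # pEC50_test - pEC50_ref
    rai: np.ndarray           # (Span/EC50)_test / (Span/EC50)_ref

    @property
    def emax_mean(self) -> float:
        return float(np.mean(self.emax))

    @property
    def delta_pec50_mean(self) -> float:
        return float(np.mean(self.delta_pec50))

    @property
    def rai_mean(self) -> float:
        return float(np.mean(self.rai))

    def summary(self) -> str:
        return (
            "Relative activity (test vs reference)\n"
            f"  Emax       : {self.emax_mean:.4g} (per-replicate {np.round(self.emax, 4).tolist()})\n"
            f"  dpEC50     : {self.delta_pec50_mean:.4g}\n"
            f"  RAi        : {self.rai_mean:.4g}"
        )


def relative_activity(
    test_fits: Sequence[FourPLResults],
    reference_fits: Sequence[FourPLResults],
) -> RelativeActivity:
    """Normalize per-replicate fits by the parallel reference replicate."""
    if len(test_fits) != len(reference_fits) or not test_fits:
        raise ValueError(
            "test and reference need the same (non-zero) number of "
            "replicate fits, matched by experiment index"
        )
    emax, dp, rai = [], [], []
    for t, r in zip(test_fits, reference_fits):
        if not (t.converged and r.converged):
            raise ValueError("relative activity requires converged fits")
        if r.span <= 0:
            raise ValueError("reference Span must be positive")
        emax.append(t.span / r.span)
        dp.append(t.pec50 - r.pec50)
        rai.append((t.span / t.ec50) / (r.span / r.ec50))
    return RelativeActivity(np.array(emax), np.array(dp), np.array(rai))


def significance_stars(p: float | None) -> str:
    if p is None:
        return "n/a"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class BiasResult:
    """ddLog(Emax/EC50) ligand bias between two pathways.

    Per replicate, dLog = log10(Span/EC50)_test - log10(Span/EC50)_reference
    within a pathway; ddLog = dLog(pathway A) - dLog(pathway B). The
    one-sample t-test (two-sided) asks whether ddLog differs from 0.
    """

    pathway_a: str
    pathway_b: str
    dlog_a: np.ndarray
    dlog_b: np.ndarray
    ddlog_per_replicate: np.ndarray
    t: float | None
    df: int | None
    p: float | None

    @property
    def ddlog(self) -> float:
        return float(np.mean(self.ddlog_per_replicate))

    @property
    def ddlog_of_means(self) -> float:
        """ddLog computed from per-replicate dLog means (alternate convention)."""
        return float(np.mean(self.dlog_a) - np.mean(self.dlog_b))

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    def summary(self) -> str:
        return (
            f"Ligand bias ddLog(Emax/EC50): {self.pathway_a} vs {self.pathway_b}\n"
            f"  dLog {self.pathway_a:10s}: {np.round(self.dlog_a, 4).tolist()}\n"
            f"  dLog {self.pathway_b:10s}: {np.round(self.dlog_b, 4).tolist()}\n"
            f"  ddLog per rep : {np.round(self.ddlog_per_replicate, 4).tolist()}\n"
            f"  ddLog (mean)  : {self.ddlog:.4g}\n"
            + (
                f"  t = {self.t:.4g}, df = {self.df}, p = {self.p:.4g} ({self.stars})"
                if self.t is not None
                else "  t-test not computed (< 2 replicates)"
            )
        )


def bias_factor(
    test_fits: dict[str, Sequence[FourPLResults]],
    reference_fits: dict[str, Sequence[FourPLResults]],
    pathway_a: str,
    pathway_b: str,
) -> BiasResult:
    """Ligand bias of a test ligand against a reference ligand.

    ``test_fits`` / ``reference_fits`` map pathway name to per-replicate 4PL
    fits; replicates are matched by experiment index (assays run in
    parallel). A bias toward ``pathway_a`` gives positive ddLog.
    """
    dlogs = {}
    for pw in (pathway_a, pathway_b):
        tf = list(test_fits[pw])
        rf = list(reference_fits[pw])
        if len(tf) != len(rf) or not tf:
            raise ValueError(
                f"pathway {pw!r}: replicate counts differ between test and "
                "reference (matching is by experiment index)"
            )
        dlogs[pw] = np.array(
            [t.log_span_over_ec50 - r.log_span_over_ec50 for t, r in zip(tf, rf)]
        )
    if len(dlogs[pathway_a]) != len(dlogs[pathway_b]):
        raise ValueError("pathways have different replicate counts")
    dd = dlogs[pathway_a] - dlogs[pathway_b]
    if len(dd) >= 2:
        df = len(dd) - 1
        if np.std(dd, ddof=1) < 1e-14 * max(1.0, np.abs(dd).max()):
            # identical replicates: zero variance, the t statistic is undefined
            t = p = None
        else:
            t_res = stats.ttest_1samp(dd, 0.0)
            t, p = float(t_res.statistic), float(t_res.pvalue)
    else:
        t = df = p = None
    return BiasResult(
        pathway_a, pathway_b, dlogs[pathway_a], dlogs[pathway_b], dd, t,
        df if df is not None else (len(dd) - 1 if len(dd) >= 2 else None), p,
    )


# ---------------------------------------------------------------------------
# radioligand binding


@dataclass
class SaturationResults:
    """One-site specific binding fit: B = Bmax * L / (Kd + L)."""

    bmax: float
    kd: float           # molar
    bmax_ci: tuple[float, float]
    kd_ci: tuple[float, float]
    rss: float
    n_obs: int
    converged: bool
    n_negative_specific: int = 0

    @property
    def kd_nM(self) -> float:
        return self.kd * 1e9

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.bmax * conc / (self.kd + conc)

    def summary(self) -> str:
        return (
            "One-site saturation binding fit\n"
            f"  n_obs   : {self.n_obs}"
            + (
                f"  ({self.n_negative_specific} negative specific counts retained)\n"
                if self.n_negative_specific
                else "\n"
            )
            + f"  Bmax    : {self.bmax:.6g}  (95% CI {self.bmax_ci[0]:.6g} .. {self.bmax_ci[1]:.6g})\n"
            f"  Kd (nM) : {self.kd_nM:.6g}  (95% CI {self.kd_ci[0] * 1e9:.6g} .. {self.kd_ci[1] * 1e9:.6g})"
        )


class SaturationBinding:
    """One-site saturation binding model on total/nonspecific count pairs."""

    def __init__(self, conc, counts_total, counts_nonspecific):
        conc = np.asarray(conc, dtype=float)
        total = np.asarray(counts_total, dtype=float)
        ns = np.asarray(counts_nonspecific, dtype=float)
        if not (conc.shape == total.shape == ns.shape):
            raise ValueError("conc/total/nonspecific must be matched arrays")
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 radioligand concentrations")
        self.conc = conc
        self.specific = total - ns   # replicate-matched; negatives retained

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SaturationBinding":
        sub = df[df["mode"] == "saturation"] if "mode" in df.columns else df
        if sub.empty:
            raise ValueError("no saturation-mode rows in binding table")
        return cls(
            sub["conc_M"].to_numpy(),
            sub["counts_total"].to_numpy(),
            sub["counts_nonspecific"].to_numpy(),
        )

    def fit(self) -> SaturationResults:
        L, B = self.conc, self.specific
        n_neg = int(np.sum(B < 0))
        if np.all(B <= 0):
            raise ValueError("all specific counts are non-positive; no binding signal")

        def resid(p):
            bmax, kd = p
            return bmax * L / (kd + L) - B

        p0 = np.array([max(B.max(), 1e-9), np.median(L)])
        sol = optimize.least_squares(
            resid, p0, bounds=([0, 1e-15], [np.inf, np.inf]),
            x_scale=np.abs(p0),  # Bmax (counts) and Kd (molar) differ wildly
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        bmax, kd = sol.x
        rss = float(2 * sol.cost)
        cov = _cov_from_jac(sol.jac, rss, len(B), 2)
        if cov is not None:
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            z = stats.norm.ppf(0.975)
            bmax_ci = (bmax - z * se[0], bmax + z * se[0])
            kd_ci = (kd - z * se[1], kd + z * se[1])
        else:
            bmax_ci = kd_ci = (float("nan"), float("nan"))
        return SaturationResults(
            float(bmax), float(kd), bmax_ci, kd_ci, rss, len(B),
            bool(sol.success), n_neg,
        )


def cheng_prusoff(ic50: float, radioligand_conc: float, kd: float) -> float:
    """Ki = IC50 / (1 + L/Kd); all concentrations molar."""
    if radioligand_conc <= 0 or kd <= 0:
        raise ValueError("radioligand concentration and Kd must be positive")
    return ic50 / (1.0 + radioligand_conc / kd)


@dataclass
class CompetitionResults:
    """Sigmoid competition fit in log(inhibitor) with Cheng-Prusoff Ki."""

    top: float
    bottom: float
    ic50: float          # molar
    hill: float          # descending curves give negative slope in the 4PL form
    radioligand_conc: float
    radioligand_kd: float
    rss: float
    n_obs: int
    converged: bool

    @property
    def ki(self) -> float:
        return cheng_prusoff(self.ic50, self.radioligand_conc, self.radioligand_kd)

    @property
    def ki_nM(self) -> float:
        return self.ki * 1e9

    def summary(self) -> str:
        return (
            "Competition binding fit\n"
            f"  Top/Bottom : {self.top:.6g} / {self.bottom:.6g}\n"
            f"  IC50 (nM)  : {self.ic50 * 1e9:.6g}\n"
            f"  HillSlope  : {self.hill:.6g}\n"
            f"  Ki (nM)    : {self.ki_nM:.6g}  "
            f"[Cheng-Prusoff, L = {self.radioligand_conc * 1e9:.3g} nM, "
            f"Kd = {self.radioligand_kd * 1e9:.3g} nM]"
        )


class CompetitionBinding:
    """Competition binding model: specific counts vs inhibitor concentration.

    ``radioligand_conc`` (L) and ``radioligand_kd`` (Kd) are the assay
    radioligand concentration and its affinity, both molar, used for the
    Cheng-Prusoff conversion of the fitted IC50 into Ki.
    """

    def __init__(self, conc, specific, radioligand_conc: float, radioligand_kd: float):
        if radioligand_conc <= 0 or radioligand_kd <= 0:
            raise ValueError("radioligand concentration and Kd must be positive")
        conc = np.asarray(conc, dtype=float)
        y = np.asarray(specific, dtype=float)
        if conc.shape != y.shape:
            raise ValueError("conc and specific counts must be matched")
        if np.any(conc <= 0):
            raise ValueError("inhibitor concentrations must be positive")
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 inhibitor concentrations")
        self.conc = conc
        self.specific = y
        self.L = float(radioligand_conc)
        self.kd = float(radioligand_kd)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, radioligand_conc: float, radioligand_kd: float
    ) -> "CompetitionBinding":
        sub = df[df["mode"] == "competition"] if "mode" in df.columns else df
        if sub.empty:
            raise ValueError("no competition-mode rows in binding table")
        specific = sub["counts_total"].to_numpy() - sub["counts_nonspecific"].to_numpy()
        return cls(sub["conc_M"].to_numpy(), specific, radioligand_conc, radioligand_kd)

    def fit(self, hill_bound: float = 5.0) -> CompetitionResults:
        logc = np.log10(self.conc)
        starts = list(np.linspace(logc.min(), logc.max(), 5))
        params, rss, ok, jac = _logistic_least_squares(
            logc, self.specific, hill_bound, starts
        )
        b, t, le, h = params
        # the 4PL is invariant under (b, t, h) -> (t, b, -h); orient so that
        # ``top`` is the zero-inhibitor plateau (h <= 0 in the standard form)
        if h > 0:
            b, t, h = t, b, -h
        return CompetitionResults(
            top=float(t), bottom=float(b), ic50=float(10.0 ** le),
            hill=float(-h), radioligand_conc=self.L, radioligand_kd=self.kd,
            rss=rss, n_obs=len(self.specific), converged=ok,
        )
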