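"""Recombination-event counting and distribution statistics.

An RE count for one individual on one chromosome is the number of maximal
runs of consecutive hDNA-positive loci along the marker order (minimum-event
parsimony: one event explains a run of adjacent positive loci), with one
exception: a run whose adjacent marker pair straddles the centromere
interval is split into two events, one per chromosome arm, because
recombination near the centromere is rare enough that a single event
spanning it is implausible. Missing loci are dropped before the run
analysis, so adjacency is defined on observed loci.

The population distribution of RE counts is summarised by a Gaussian peak
model

    y = y0 + A / (w * sqrt(pi/2)) * exp(-2 (x - x_c)^2 / w^2)

fitted to the proportions p_k by nonlinear least squares. Here x_c is the
mean event count, w = 2*sigma, FWHM = sqrt(2 ln 2) * w, and the integral of
the fitted curve over [x_c - sigma, x_c + sigma] gives the probability mass
of the central +/- 1 sd band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .calling import HdnaCall
from .genome import ChromosomeModel, MarkerPanel, ValidationError
from .linfit import LinearFitResult, linear_fit

FWHM_FACTOR = math.sqrt(2.0 * math.log(2.0))  # FWHM = FWHM_FACTOR * w = 2*sqrt(2 ln2)*sigma


def fwhm_from_width(w: float) -> float:
    """Full width at half maximum of the Gaussian peak, from its width parameter w."""
    return FWHM_FACTOR * w


# ---------------------------------------------------------------------------
# RE counting

def _spanning_pair_index(positions: np.ndarray, chrom: ChromosomeModel) -> int | None:
    """Index j such that the observed pair (j, j+1) straddles the centromere.

    Requires pos[j] left of the interval and pos[j+1] at or beyond its right
    edge; at most one such pair exists (none when a marker lies inside the
    interval).
    """
    spans = (positions[:-1] < chrom.centromere_start_bp) & (
        positions[1:] >= chrom.centromere_end_bp
    )
    idx = np.flatnonzero(spans)
    return int(idx[0]) if len(idx) else None


def count_res(
    calls: Sequence[str | bool],
    positions_bp: Sequence[int],
    chrom: ChromosomeModel,
) -> int:
    """RE count for one individual from its ordered per-locus hDNA calls.

    ``calls`` may be booleans or {'present','absent','missing'} strings;
    missing loci are dropped first. Positions must be strictly increasing.
    """
    positions = np.asarray(positions_bp, dtype=np.int64)
    if len(positions) != len(calls):
        raise ValidationError("calls and positions length mismatch")
    if np.any(np.diff(positions) <= 0):
        raise ValidationError("positions must be strictly increasing")
    keep, present = [], []
    for c in calls:
        if isinstance(c, (bool, np.bool_)):
            keep.append(True)
            present.append(bool(c))
        elif c == HdnaCall.MISSING.value:
            keep.append(False)
            present.append(False)
        else:
            keep.append(True)
            present.append(c == HdnaCall.PRESENT.value)
    keep = np.asarray(keep)
    p = np.asarray(present)[keep]
    pos = positions[keep]
    if len(p) == 0:
        return 0
    runs = int(p[0]) + int(np.sum(p[1:] & ~p[:-1]))
    j = _spanning_pair_index(pos, chrom)
    if j is not None and p[j] and p[j + 1]:
        runs += 1  # the straddling run is split into one event per arm
    return runs


def count_res_population(
    call_matrix: pd.DataFrame,
    panel: MarkerPanel,
    chrom: ChromosomeModel,
) -> pd.Series:
    """RE count per individual, for the panel's loci on one chromosome.

    ``call_matrix`` is the calling module's present/absent/missing matrix
    (individuals x marker ids). Columns are reordered to genomic order.
    """
    loci = panel.on_chromosome(chrom.name)
    ids = [m for m in loci.marker_ids if m in call_matrix.columns]
    if not ids:
        raise ValidationError(f"no call columns on {chrom.name}")
    sub = call_matrix[ids]
    positions = np.array([panel[m].pos_bp for m in ids], dtype=np.int64)

    vals = sub.to_numpy()
    any_missing = np.any(vals == HdnaCall.MISSING.value)
    if not any_missing:
        p = vals == HdnaCall.PRESENT.value
        runs = p[:, 0].astype(int) + np.sum(p[:, 1:] & ~p[:, :-1], axis=1)
        j = _spanning_pair_index(positions, chrom)
        if j is not None:
            runs = runs + (p[:, j] & p[:, j + 1]).astype(int)
        return pd.Series(runs, index=sub.index, name="re_count")
    counts = [
        count_res(vals[i], positions, chrom) for i in range(vals.shape[0])
    ]
    return pd.Series(counts, index=sub.index, name="re_count")


def re_distribution(counts: Sequence[int]) -> pd.Series:
    """Proportion of individuals with each observed RE count (sums to 1)."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValidationError("empty population")
    ks, freqs = np.unique(counts, return_counts=True)
    return pd.Series(freqs / counts.size, index=ks, name="proportion")


# ---------------------------------------------------------------------------
# Normality

@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False
    note: str = (
        "one-sample K-S with parameters estimated from the sample is "
        "anti-conservative (Lilliefors bias); use lilliefors=True for the "
        "corrected p-value"
    )


def test_normality(counts: Sequence[int], lilliefors: bool = False) -> NormalityResult:
    """One-sample Kolmogorov-Smirnov test against Normal(sample mean, sample sd).

    Requires n >= 5. A constant sample returns a degenerate-flagged result.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 5:
        raise ValidationError(f"normality test needs n >= 5, got {counts.size}")
    if np.ptp(counts) == 0:
        return NormalityResult(float("nan"), float("nan"), "ks", degenerate=True)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(counts, dist="norm")
        return NormalityResult(float(stat), float(p), "lilliefors")
    mean, sd = counts.mean(), counts.std(ddof=1)
    stat, p = stats.kstest(counts, "norm", args=(mean, sd))
    return NormalityResult(float(stat), float(p), "ks")


# ---------------------------------------------------------------------------
# Gaussian peak model

def gaussian_peak(x, y0: float, area: float, x_c: float, w: float):
    """Baseline-plus-Gaussian: y0 + A/(w sqrt(pi/2)) exp(-2 (x-x_c)^2 / w^2)."""
    x = np.asarray(x, dtype=float)
    return y0 + area / (w * math.sqrt(math.pi / 2.0)) * np.exp(
        -2.0 * (x - x_c) ** 2 / w**2
    )


@dataclass(frozen=True)
class GaussianPeakResults:
    """Fitted Gaussian peak: parameters, uncertainties and diagnostics."""

    y0: float
    area: float
    x_c: float
    w: float
    stderr: dict[str, float]
    r_squared: float
    nobs: int
    converged: bool
    message: str = ""

    @property
    def sigma(self) -> float:
        return self.w / 2.0

    @property
    def fwhm(self) -> float:
        return fwhm_from_width(self.w)

    def predict(self, x):
        return gaussian_peak(x, self.y0, self.area, self.x_c, self.w)

    def integral_pm_sigma(self, include_baseline: bool = True) -> float:
        """Quadrature of the fitted curve over [x_c - sigma, x_c + sigma].

        With ``include_baseline=False`` the y0 offset is excluded, leaving
        the pure Gaussian mass A*erf(1/sqrt(2)).
        """
        lo, hi = self.x_c - self.sigma, self.x_c + self.sigma
        val, _ = integrate.quad(
            lambda x: gaussian_peak(x, self.y0, self.area, self.x_c, self.w), lo, hi
        )
        if not include_baseline:
            val -= self.y0 * (hi - lo)
        return float(val)

    def as_dict(self) -> dict[str, float]:
        return {
            "y0": self.y0,
            "A": self.area,
            "x_c": self.x_c,
            "w": self.w,
            "sigma": self.sigma,
            "FWHM": self.fwhm,
            "R2": self.r_squared,
            "integral_pm_sigma": self.integral_pm_sigma(),
            "integral_pm_sigma_no_baseline": self.integral_pm_sigma(False),
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Gaussian peak fit (nonlinear least squares)",
            f"  observations: {self.nobs}    converged: {self.converged}",
            f"  {'param':>6} {'value':>12} {'std err':>12}",
        ]
        for name, val in (("y0", self.y0), ("A", self.area),
                          ("x_c", self.x_c), ("w", self.w)):
            se = self.stderr.get(name, float("nan"))
            lines.append(f"  {name:>6} {val:12.6g} {se:12.4g}")
        lines += [
            f"  sigma = {self.sigma:.6g}   FWHM = {self.fwhm:.6g}   R2 = {self.r_squared:.6g}",
            f"  integral over x_c +/- sigma = {self.integral_pm_sigma():.6g}",
        ]
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)


class GaussianPeakModel:
    """Gaussian peak fitted to an RE-count histogram (k, p_k).

    Accepts a proportion Series (index = counts) or explicit x/y arrays.
    ``fit()`` returns :class:`GaussianPeakResults`; non-convergence returns a
    results object flagged ``converged=False`` carrying the solver message.
    """

    def __init__(self, proportions: pd.Series | None = None,
                 x=None, y=None):
        if proportions is not None:
            x = proportions.index.to_numpy(dtype=float)
            y = proportions.to_numpy(dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValidationError("x and y length mismatch")
        if len(np.unique(self.x)) < 4:
            raise ValidationError(
                f"Gaussian fit needs >= 4 distinct bins for 4 parameters, "
                f"got {len(np.unique(self.x))}"
            )

    def _initial_guess(self) -> tuple[float, float, float, float]:
        y0 = max(float(self.y.min()), 0.0)
        ypos = np.clip(self.y - y0, 0.0, None)
        wsum = float(ypos.sum())
        if wsum <= 0:
            return y0, 1.0, float(self.x.mean()), float(max(np.ptp(self.x) / 2, 1.0))
        xc = float(np.sum(self.x * ypos) / wsum)
        sd = math.sqrt(max(float(np.sum((self.x - xc) ** 2 * ypos) / wsum), 0.09))
        dx = float(np.median(np.diff(np.sort(self.x)))) if len(self.x) > 1 else 1.0
        return y0, max(wsum * dx, 1e-3), xc, 2.0 * sd

    def fit(self) -> GaussianPeakResults:
        p0 = self._initial_guess()
        # y0 >= 0: a proportion histogram has no negative baseline, and an
        # unbounded y0 lets sparse histograms drift to a degenerate broad
        # Gaussian on a negative offset; the box on x_c / w keeps the peak
        # within (a span of) the data
        span = float(max(np.ptp(self.x), 1.0))
        bounds = (
            [0.0, 1e-12, float(self.x.min()) - span, 1e-12],
            [float(self.y.max()), 10.0, float(self.x.max()) + span, 4.0 * span],
        )
        try:
            popt, pcov = optimize.curve_fit(
                gaussian_peak, self.x, self.y, p0=p0, bounds=bounds,
                maxfev=10000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
            nanerr = {k: float("nan") for k in ("y0", "A", "x_c", "w")}
            return GaussianPeakResults(
                y0=p0[0], area=p0[1], x_c=p0[2], w=p0[3], stderr=nanerr,
                r_squared=float("nan"), nobs=len(self.x), converged=False,
                message=f"fit failed: {exc}",
            )
        resid = self.y - gaussian_peak(self.x, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        perr = np.sqrt(np.diag(pcov))
        return GaussianPeakResults(
            y0=float(popt[0]), area=float(popt[1]), x_c=float(popt[2]), w=float(popt[3]),
            stderr=dict(zip(("y0", "A", "x_c", "w"), map(float, perr))),
            r_squared=r2, nobs=len(self.x), converged=True,
        )


def fit_gaussian(proportions: pd.Series) -> GaussianPeakResults:
    """Fit the Gaussian peak model to an RE proportion histogram."""
    return GaussianPeakModel(proportions).fit()


def integral_pm_sigma(fit: GaussianPeakResults, include_baseline: bool = True) -> float:
    return fit.integral_pm_sigma(include_baseline=include_baseline)


# ---------------------------------------------------------------------------
# Marker subsampling (ascertainment analysis)

@dataclass(frozen=True)
class SubsampleScheme:
    sizes: tuple[int, ...] = (14, 24, 41, 60, 79)
    reps: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if any(s < 1 for s in self.sizes):
            raise ValidationError("panel sizes must be >= 1")


def subsample_analysis(
    call_matrix: pd.DataFrame,
    panel: MarkerPanel,
    chrom: ChromosomeModel,
    scheme: SubsampleScheme,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-density ascertainment: recompute RE fits on random marker subsets.

    For each panel size and replicate, draws that many markers uniformly
    without replacement (genomic order preserved), recomputes per-individual
    RE counts and the Gaussian fit. Returns (summary, fits): ``summary`` has
    one row per size with the mean fitted x_c and mean RE count across
    replicates; ``fits`` has one row per (size, rep). Replicate RNG streams
    are derived from (seed, size index, rep), so every subset is reproducible.
    """
    loci = panel.on_chromosome(chrom.name)
    avail = [m for m in loci.marker_ids if m in call_matrix.columns]
    if max(scheme.sizes) > len(avail):
        raise ValidationError(
            f"subsample size {max(scheme.sizes)} exceeds panel size {len(avail)}"
        )
    fit_rows = []
    for si, size in enumerate(scheme.sizes):
        for rep in range(scheme.reps):
            rng = np.random.default_rng([scheme.seed, si, rep])
            if size == len(avail):
                chosen = list(avail)
            else:
                chosen = [avail[i] for i in sorted(rng.choice(len(avail), size, replace=False))]
            sub_panel = panel.subset(chosen)
            counts = count_res_population(call_matrix[chosen], sub_panel, chrom)
            dist = re_distribution(counts)
            row = {"size": size, "rep": rep, "mean_re": float(counts.mean())}
            if len(dist) >= 4:
                res = fit_gaussian(dist)
                row.update(res.as_dict())
            else:
                row.update({"converged": False})
            fit_rows.append(row)
    fits = pd.DataFrame(fit_rows)
    conv = fits[fits["converged"] == True]  # noqa: E712
    summary = (
        conv.groupby("size")
        .agg(mean_xc=("x_c", "mean"), mean_re=("mean_re", "mean"),
             n_converged=("rep", "count"))
        .reset_index()
        .sort_values("size")
        .reset_index(drop=True)
    )
    return summary, fits


def regress_xc_vs_nmarkers(points: Sequence[tuple[float, float]]) -> LinearFitResult:
    """OLS of the fitted mean RE count x_c on the number of markers used."""
    if len(points) < 3:
        raise ValidationError("need >= 3 (n_markers, x_c) points")
    n, xc = zip(*points)
    return linear_fit(n, xc)
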