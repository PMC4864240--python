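"""Competitive fluorescence binding assay analysis.

Affinity of a ligand for a chemosensory protein (CSP) is measured by
displacement of the fluorescent reporter 1-NPN (N-phenyl-1-naphthylamine).
Two kinds of series are analysed:

* **Saturation titration** — protein titrated with increasing probe
  concentrations; a one-site model ``I = Bmax * c / (K + c)`` yields the
  probe dissociation constant ``K`` (``k_probe``), either by nonlinear
  least squares or by Scatchard linearization (bound/free vs bound,
  slope = -1/K).
* **Competition** — fixed probe, increasing competitor; percent residual
  fluorescence follows ``100 * (P + K) / (P + K * (1 + L/Ki))`` where
  ``P`` is the probe concentration and ``K`` the probe constant.  The
  half-displacement point of this model is ``IC50 = Ki * (1 + P/K)``,
  so the classic conversion ``Ki = IC50 / (1 + P/K)`` inverts it exactly.

All concentrations are micromolar throughout; no unit inference is done.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitError",
    "SaturationSeries",
    "SaturationFit",
    "CompetitionSeries",
    "CompetitionFit",
    "AffinityResult",
    "normalize_fluorescence",
    "saturation_intensity",
    "competition_percent",
    "fit_saturation",
    "fit_competition",
    "ki_from_ic50",
    "affinity_from_fit",
    "build_affinity_table",
]

#: IC50 above which the binding constant is not reported ("u.d.").
DEFAULT_UNDETERMINED_THRESHOLD = 100.0


class FitError(RuntimeError):
    """A least-squares fit did not converge or produced an unphysical estimate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SaturationSeries:
    """Probe-concentration / fluorescence-intensity pairs for one protein.

    Parameters
    ----------
    protein_id : str
        Identifier of the protein being titrated.
    probe_conc : sequence of float
        Probe (1-NPN) concentrations, μM; strictly positive, strictly
        increasing.
    intensity : sequence of float
        Fluorescence readings, arbitrary units; non-negative.
    protein_conc : float
        Protein concentration in the cuvette, μM (assay default 2).
    """

    protein_id: str
    probe_conc: np.ndarray
    intensity: np.ndarray
    protein_conc: float = 2.0

    def __post_init__(self) -> None:
        self.probe_conc = np.asarray(self.probe_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.probe_conc.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("probe_conc and intensity must be 1-D")
        if len(self.probe_conc) != len(self.intensity):
            raise ValueError("probe_conc and intensity lengths differ")
        if len(self.probe_conc) < 4:
            raise ValueError("need at least 4 titration points")
        if not np.all(self.probe_conc > 0):
            raise ValueError("probe concentrations must be strictly positive")
        if not np.all(np.diff(self.probe_conc) > 0):
            raise ValueError("probe concentrations must be strictly increasing")
        if not np.all(self.intensity >= 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.probe_conc)


@dataclass(frozen=True)
class SaturationFit:
    """One-site saturation fit: probe dissociation constant and plateau."""

    k_probe: float          # μM
    b_max: float            # AU
    method: str             # "nonlinear" | "scatchard"
    goodness: float         # R^2 of the fitted relation

    def __post_init__(self) -> None:
        if not (self.k_probe > 0 and math.isfinite(self.k_probe)):
            raise FitError(f"non-positive probe constant: {self.k_probe}")
        if not (self.b_max > 0 and math.isfinite(self.b_max)):
            raise FitError(f"non-positive saturation plateau: {self.b_max}")


@dataclass(eq=False)
class CompetitionSeries:
    """Competitor-concentration / percent-fluorescence pairs.

    ``percent_fluorescence`` is expressed relative to the zero-competitor
    reading (100 = no displacement).  Concentrations are μM, non-negative
    and strictly increasing; a leading 0 μM row is allowed.
    """

    protein_id: str
    ligand_id: str
    competitor_conc: np.ndarray
    percent_fluorescence: np.ndarray
    probe_conc: float = 2.0

    def __post_init__(self) -> None:
        self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
        self.percent_fluorescence = np.asarray(self.percent_fluorescence, dtype=float)
        if len(self.competitor_conc) != len(self.percent_fluorescence):
            raise ValueError("concentration and percent arrays differ in length")
        if not np.all(self.competitor_conc >= 0):
            raise ValueError("competitor concentrations must be non-negative")
        if not np.all(np.diff(self.competitor_conc) > 0):
            raise ValueError("competitor concentrations must be strictly increasing")
        if np.any(self.percent_fluorescence < 0) or np.any(self.percent_fluorescence > 120):
            raise ValueError("percent fluorescence must lie in [0, 120]")

    def __len__(self) -> int:
        return len(self.competitor_conc)


@dataclass(frozen=True)
class CompetitionFit:
    """Result of a displacement-curve fit.

    ``status`` is one of ``determined`` (IC50 within the reporting
    threshold), ``undetermined`` (IC50 above the threshold or no 50%
    crossing — rendered "u.d." downstream) or ``failed`` (no displacement).
    """

    ic50: Optional[float]   # μM; None when not estimable
    hill: float
    top: float
    bottom: float
    status: str
    goodness: float = float("nan")

    def __post_init__(self) -> None:
        if self.status not in ("determined", "undetermined", "failed"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "determined" and not (self.ic50 and self.ic50 > 0):
            raise ValueError("determined fit requires positive ic50")


@dataclass(frozen=True)
class AffinityResult:
    """IC50/Ki record for one protein-ligand pair."""

    protein_id: str
    ligand_id: str
    ic50: Optional[float]
    ki: Optional[float]
    k_probe: float
    probe_conc: float
    status: str


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def saturation_intensity(conc, b_max: float, k_probe: float):
    """One-site binding curve ``Bmax * c / (K + c)``."""
    conc = np.asarray(conc, dtype=float)
    return b_max * conc / (k_probe + conc)


def competition_percent(conc, ki: float, probe_conc: float = 2.0,
                        k_probe: float = 11.66):
    """Percent residual probe fluorescence under competitive displacement.

    ``100 * (P + K) / (P + K * (1 + L/Ki))`` — a one-site competition model
    whose half-displacement concentration is exactly ``Ki * (1 + P/K)``.
    """
    conc = np.asarray(conc, dtype=float)
    p, k = probe_conc, k_probe
    return 100.0 * (p + k) / (p + k * (1.0 + conc / ki))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def normalize_fluorescence(raw_intensities: Sequence[float],
                           reference_intensity: float) -> np.ndarray:
    """Express raw intensities as percent of the zero-competitor reference.

    Raises ``ValueError`` for a zero or negative reference (unusable blank).
    """
    if not (reference_intensity > 0):
        raise ValueError(
            f"reference intensity must be positive, got {reference_intensity}")
    return 100.0 * np.asarray(raw_intensities, dtype=float) / reference_intensity


def fit_saturation(series: SaturationSeries,
                   method: str = "nonlinear") -> SaturationFit:
    """Estimate the probe dissociation constant from a titration.

    ``method="nonlinear"`` fits ``I = Bmax*c/(K+c)`` by least squares;
    ``method="scatchard"`` regresses bound/free (``I/c``) on bound (``I``),
    whose slope is ``-1/K``.  Either raises :class:`FitError` on degenerate
    input (e.g. constant intensity) or a non-positive estimate.
    """
    if method not in ("nonlinear", "scatchard"):
        raise ValueError(f"unknown method {method!r}")
    c = series.probe_conc
    y = series.intensity
    if np.ptp(y) == 0:
        raise FitError("intensity is constant across the titration")

    if method == "nonlinear":
        p0 = (float(y.max()) or 1.0, float(np.median(c)))
        try:
            popt, pcov = optimize.curve_fit(
                lambda cc, b, k: saturation_intensity(cc, b, k),
                c, y, p0=p0, bounds=([0.0, 1e-9], [np.inf, np.inf]),
                maxfev=10000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"saturation fit did not converge: {exc}") from exc
        if not np.all(np.isfinite(popt)):
            raise FitError("saturation fit returned non-finite parameters")
        b_max, k_probe = popt
        resid = y - saturation_intensity(c, b_max, k_probe)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
        return SaturationFit(k_probe=float(k_probe), b_max=float(b_max),
                             method=method, goodness=r2)

    # Scatchard: y/c = (Bmax - y)/K -> linear in y with slope -1/K
    bound = y
    ratio = y / c
    if np.ptp(bound) == 0:
        raise FitError("Scatchard regression is degenerate (constant bound)")
    reg = stats.linregress(bound, ratio)
    if not (reg.slope < 0 and math.isfinite(reg.slope)):
        raise FitError(f"Scatchard slope non-negative ({reg.slope}); "
                       "no one-site binding signal")
    k_probe = -1.0 / reg.slope
    b_max = reg.intercept * k_probe
    return SaturationFit(k_probe=float(k_probe), b_max=float(b_max),
                         method=method, goodness=float(reg.rvalue ** 2))


def _logistic4(logc, log_ic50, hill, top, bottom):
    # decreasing 4-parameter logistic in log10 concentration; the midpoint
    # (top+bottom)/2 is reached exactly at log_ic50
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def _interpolate_ic50(conc: np.ndarray, pct: np.ndarray,
                      target: float = 50.0) -> Optional[float]:
    """Log-linear interpolation of the concentration where pct crosses target.

    Scans ascending concentrations for the first bracketing pair; a point
    at exactly the target takes the lower concentration.  Returns None when
    no crossing exists.
    """
    for i in range(len(conc)):
        if pct[i] == target and conc[i] > 0:
            return float(conc[i])
        if i + 1 < len(conc) and pct[i] > target >= pct[i + 1]:
            c1, c2 = conc[i], conc[i + 1]
            y1, y2 = pct[i], pct[i + 1]
            if c1 <= 0:  # cannot log-interpolate from zero; fall back to linear
                return float(c1 + (c2 - c1) * (y1 - target) / (y1 - y2))
            lx = np.log10(c1) + (np.log10(c2) - np.log10(c1)) * (y1 - target) / (y1 - y2)
            return float(10.0 ** lx)
    return None


def fit_competition(series: CompetitionSeries,
                    undetermined_threshold: float = DEFAULT_UNDETERMINED_THRESHOLD,
                    top: Optional[float] = 100.0) -> CompetitionFit:
    """Fit a displacement curve and extract IC50 with the reporting rule.

    A logistic in log10 concentration is fitted with the top plateau fixed
    at 100 (percent is *defined* relative to the zero-competitor reference,
    so the plateau is 100 by construction; pass ``top=None`` to fit it
    freely in [80, 120] instead), bottom bounded in [0, 50] and Hill slope
    initialized at 1.  ``IC50`` is the concentration at the midpoint
    between top and bottom.  When the sigmoid fit fails but the data cross
    50%, a log-linear interpolation between the bracketing points supplies
    IC50.  Fits with IC50 above ``undetermined_threshold`` (assay rule:
    100 μM), or data that never reach 50%, are flagged ``undetermined``;
    curves showing no net displacement are ``failed``.
    """
    conc = series.competitor_conc
    pct = series.percent_fluorescence
    if len(conc) < 4:
        raise ValueError("need at least 4 competition points")

    top0 = float(np.mean(pct[:2]))
    if pct[-1] >= pct[0]:  # monotonically non-decreasing: no displacement
        return CompetitionFit(ic50=None, hill=float("nan"), top=top0,
                              bottom=float("nan"), status="failed")

    crossing = bool(np.any(pct <= 50.0))
    mask = conc > 0
    x = np.log10(conc[mask])
    y = pct[mask]

    fit_ok = False
    ic50 = hill = top_hat = bottom = r2 = float("nan")
    if mask.sum() >= 4:
        bottom_init = float(np.clip(y.min(), 0.0, 50.0))
        l0 = _interpolate_ic50(conc, pct,
                               target=(min(top or top0, 100.0) + bottom_init) / 2.0)
        log_ic50_0 = np.log10(l0) if l0 else float(np.median(x))
        if top is None:
            model = _logistic4
            p0 = [log_ic50_0, 1.0, float(np.clip(top0, 80.0, 120.0)), bottom_init]
            lo, hi = ([x.min() - 3.0, 0.2, 80.0, 0.0],
                      [x.max() + 3.0, 5.0, 120.0, 50.0])
        else:
            def model(logc, log_ic50, hill_, bottom_):
                return _logistic4(logc, log_ic50, hill_, top, bottom_)
            p0 = [log_ic50_0, 1.0, bottom_init]
            lo, hi = ([x.min() - 3.0, 0.2, 0.0], [x.max() + 3.0, 5.0, 50.0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(model, x, y, p0=p0,
                                             bounds=(lo, hi), maxfev=20000)
            ic50 = float(10.0 ** popt[0])
            hill = float(popt[1])
            top_hat = float(popt[2]) if top is None else float(top)
            bottom = float(popt[-1])
            resid = y - model(x, *popt)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
            fit_ok = np.isfinite(ic50) and ic50 > 0
        except (RuntimeError, ValueError):
            fit_ok = False

    if not fit_ok:
        # fallback: direct interpolation when the data bracket 50%
        ic50_interp = _interpolate_ic50(conc, pct) if crossing else None
        if ic50_interp is None:
            return CompetitionFit(ic50=None, hill=float("nan"), top=top0,
                                  bottom=float("nan"), status="undetermined")
        ic50, hill, top_hat, bottom, r2 = (ic50_interp, float("nan"), top0,
                                           float("nan"), float("nan"))

    if ic50 > undetermined_threshold or not crossing:
        status = "undetermined"
    else:
        status = "determined"
    return CompetitionFit(ic50=ic50, hill=hill, top=top_hat, bottom=bottom,
                          status=status, goodness=r2)


def ki_from_ic50(ic50: float, probe_conc: float, k_probe: float) -> float:
    """Convert a half-displacement concentration to an inhibition constant.

    ``Ki = IC50 / (1 + [probe]/K_probe)``, the standard correction for
    probe occupancy; with no probe present Ki equals IC50.
    """
    if k_probe <= 0:
        raise ValueError(f"probe dissociation constant must be positive, got {k_probe}")
    if ic50 < 0 or probe_conc < 0:
        raise ValueError("ic50 and probe_conc must be non-negative")
    return ic50 / (1.0 + probe_conc / k_probe)


def affinity_from_fit(series: CompetitionSeries, fit: CompetitionFit,
                      k_probe: float) -> AffinityResult:
    """Combine a competition fit with the probe constant into a Ki record."""
    ki = None
    if fit.status == "determined":
        ki = ki_from_ic50(fit.ic50, series.probe_conc, k_probe)
    return AffinityResult(protein_id=series.protein_id,
                          ligand_id=series.ligand_id,
                          ic50=fit.ic50, ki=ki, k_probe=k_probe,
                          probe_conc=series.probe_conc, status=fit.status)


def build_affinity_table(results: Sequence[AffinityResult],
                         decimals: int = 2) -> pd.DataFrame:
    """Render affinity results as a ligand × protein table.

    Determined entries show Ki (mean ± sample sd over replicate fits);
    undetermined entries show "u.d."; failed fits show "failed".  Replicates
    of one (protein, ligand) pair must agree in status.
    """
    groups: dict[tuple[str, str], list[AffinityResult]] = {}
    ligand_order: list[str] = []
    protein_order: list[str] = []
    for r in results:
        groups.setdefault((r.protein_id, r.ligand_id), []).append(r)
        if r.ligand_id not in ligand_order:
            ligand_order.append(r.ligand_id)
        if r.protein_id not in protein_order:
            protein_order.append(r.protein_id)

    cells: dict[tuple[str, str], str] = {}
    for (prot, lig), rs in groups.items():
        statuses = {r.status for r in rs}
        if len(statuses) > 1:
            raise ValueError(
                f"conflicting statuses {sorted(statuses)} for ({prot}, {lig})")
        status = statuses.pop()
        if status == "undetermined":
            cells[(lig, prot)] = "u.d."
        elif status == "failed":
            cells[(lig, prot)] = "failed"
        else:
            kis = np.array([r.ki for r in rs], dtype=float)
            if len(kis) > 1:
                cells[(lig, prot)] = (f"{kis.mean():.{decimals}f}"
                                      f"±{kis.std(ddof=1):.{decimals}f}")
            else:
                cells[(lig, prot)] = f"{kis[0]:.{decimals}f}"

    table = pd.DataFrame(index=ligand_order, columns=protein_order, dtype=object)
    for (lig, prot), text in cells.items():
        table.loc[lig, prot] = text
    table.index.name = "ligand"
    return table
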