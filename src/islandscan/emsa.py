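"""EMSA quantification: fractional saturation from band intensities and
dissociation-constant estimation by nonlinear least squares."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

KD_BOUND_FACTOR = 100.0  # upper Kd bound = 100 x max concentration


@dataclass
class BindingPoint:
    conc: float  # protein concentration, nM
    i_test: float  # unbound-band intensity in the test lane
    i_control: float  # unbound-band intensity in the zero-protein control
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError("conc must be >= 0")
        if self.i_control <= 0:
            raise ValueError("control intensity must be > 0")
        if self.i_test < 0:
            raise ValueError("test intensity must be >= 0")

    @property
    def y(self) -> float:
        return fractional_saturation(self.i_test, self.i_control)


@dataclass
class BindingCurve:
    probe_id: str
    points: list[BindingPoint] = field(default_factory=list)

    def concentrations(self) -> np.ndarray:
        return np.array(sorted({p.conc for p in self.points}))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pts = sorted(self.points, key=lambda p: (p.conc, p.replicate))
        return (np.array([p.conc for p in pts]),
                np.array([p.y for p in pts]))


@dataclass
class KdEstimate:
    probe_id: str
    kd: Optional[float]
    kd_stderr: Optional[float]
    ymax: Optional[float]
    hill_n: float
    model: str
    n_points: int
    converged: bool
    status: str = "ok"


def fractional_saturation(i_test: float, i_control: float) -> float:
    """Y = 1 - I_T / I_C. May be negative for noisy I_T > I_C (retained)."""
    if i_control <= 0:
        raise ValueError("control intensity must be > 0")
    if i_test < 0:
        raise ValueError("test intensity must be >= 0")
    return 1.0 - i_test / i_control


def _hyperbola(c, ymax, kd):
    return ymax * c / (kd + c)


def _hill(c, ymax, kd, n):
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        return ymax * c ** n / (kd ** n + c ** n)


def _init_kd(conc: np.ndarray, y: np.ndarray) -> float:
    """Concentration where linearly interpolated mean Y crosses half max Y."""
    df = pd.DataFrame({"c": conc, "y": y}).groupby("c")["y"].mean()
    cs, ys = df.index.to_numpy(float), df.to_numpy(float)
    half = ys.max() / 2.0
    for i in range(1, len(cs)):
        if ys[i - 1] < half <= ys[i]:
            frac = (half - ys[i - 1]) / (ys[i] - ys[i - 1])
            return float(cs[i - 1] + frac * (cs[i] - cs[i - 1]))
    return float(np.median(cs))


def fit_kd(curve: BindingCurve, model: str = "hyperbolic",
           fix_ymax: Optional[float] = None,
           average_replicates: bool = False) -> KdEstimate:
    """Least-squares fit of Y(c) = ymax * c^n / (Kd^n + c^n).

    The hyperbolic model fixes n = 1; the hill model fits n. Kd is bounded
    in (0, 100 x max conc]; hitting the bound or optimizer failure marks
    the estimate unconverged.
    """
    if model not in ("hyperbolic", "hill"):
        raise ValueError("model must be 'hyperbolic' or 'hill'")
    conc, y = curve.arrays()
    if average_replicates:
        df = pd.DataFrame({"c": conc, "y": y}).groupby("c", as_index=False).mean()
        conc, y = df["c"].to_numpy(), df["y"].to_numpy()
    n_points = len(conc)
    n_conc = len(np.unique(conc))
    if n_conc < 3:
        raise ValueError("need >= 3 distinct concentrations")

    def fail(status: str) -> KdEstimate:
        return KdEstimate(curve.probe_id, None, None, None,
                          1.0, model, n_points, False, status)

    ymax_obs = float(y.max())
    if ymax_obs <= 0 or not np.any(y > 0.2 * ymax_obs):
        return fail("unidentifiable: no saturation signal")

    kd0 = max(_init_kd(conc, y), 1e-9)
    kd_hi = KD_BOUND_FACTOR * float(conc.max())
    tiny = 1e-12
    try:
        if model == "hyperbolic":
            if fix_ymax is not None:
                popt, pcov = curve_fit(
                    lambda c, kd: _hyperbola(c, fix_ymax, kd), conc, y,
                    p0=[kd0], bounds=([tiny], [kd_hi]), maxfev=20000)
                kd, ymax = float(popt[0]), float(fix_ymax)
                kd_var = float(pcov[0][0])
            else:
                popt, pcov = curve_fit(
                    _hyperbola, conc, y,
                    p0=[max(ymax_obs, 0.1), kd0],
                    bounds=([tiny, tiny], [10.0, kd_hi]), maxfev=20000)
                ymax, kd = float(popt[0]), float(popt[1])
                kd_var = float(pcov[1][1])
            hill_n = 1.0
        else:
            if fix_ymax is not None:
                popt, pcov = curve_fit(
                    lambda c, kd, n: _hill(c, fix_ymax, kd, n), conc, y,
                    p0=[kd0, 1.0], bounds=([tiny, 0.1], [kd_hi, 10.0]),
                    maxfev=20000)
                kd, hill_n, ymax = float(popt[0]), float(popt[1]), float(fix_ymax)
                kd_var = float(pcov[0][0])
            else:
                popt, pcov = curve_fit(
                    _hill, conc, y,
                    p0=[max(ymax_obs, 0.1), kd0, 1.0],
                    bounds=([tiny, tiny, 0.1], [10.0, kd_hi, 10.0]),
                    maxfev=20000)
                ymax, kd, hill_n = map(float, popt)
                kd_var = float(pcov[1][1])
    except (RuntimeError, ValueError) as exc:
        return fail(f"optimizer failure: {exc}")

    if not math.isfinite(kd) or kd <= 2 * tiny or kd >= 0.999 * kd_hi:
        return fail("Kd hit optimizer bound")
    stderr = math.sqrt(kd_var) if math.isfinite(kd_var) and kd_var >= 0 else float("nan")
    return KdEstimate(curve.probe_id, kd, stderr, ymax, hill_n, model,
                      n_points, True)


def saturation_table(curve: BindingCurve) -> pd.DataFrame:
    """Per-concentration mean Y and standard error of the mean
    (SEM = sample sd / sqrt(k); NaN for a single replicate)."""
    rows = []
    conc, y = curve.arrays()
    df = pd.DataFrame({"conc": conc, "y": y})
    for c, grp in df.groupby("conc"):
        k = len(grp)
        mean = float(grp["y"].mean())
        sem = float(grp["y"].std(ddof=1) / math.sqrt(k)) if k > 1 else float("nan")
        rows.append({"conc": float(c), "mean_y": mean, "sem": sem, "n": k})
    return pd.DataFrame(rows, columns=["conc", "mean_y", "sem", "n"])


# ---------------------------------------------------------------------------
# TSV I/O

CURVE_COLUMNS = ["probe_id", "conc_nM", "replicate", "I_T", "I_C"]


def read_curves_tsv(path: str | Path) -> dict[str, BindingCurve]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {missing}")
    curves: dict[str, BindingCurve] = {}
    for _, row in df.iterrows():
        pid = str(row["probe_id"])
        curve = curves.setdefault(pid, BindingCurve(probe_id=pid))
        curve.points.append(BindingPoint(
            conc=float(row["conc_nM"]),
            i_test=float(row["I_T"]),
            i_control=float(row["I_C"]),
            replicate=int(row["replicate"]),
        ))
    return curves


def write_curves_tsv(curves: Iterable[BindingCurve], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CURVE_COLUMNS) + "\n")
        for curve in curves:
            for p in sorted(curve.points, key=lambda p: (p.conc, p.replicate)):
                fh.write(f"{curve.probe_id}\t{p.conc:g}\t{p.replicate}"
                         f"\t{p.i_test:.8g}\t{p.i_control:.8g}\n")


def fit_all(curves: dict[str, BindingCurve], model: str = "hyperbolic",
            fix_ymax: Optional[float] = None) -> pd.DataFrame:
    rows = []
    for pid in sorted(curves):
        est = fit_kd(curves[pid], model=model, fix_ymax=fix_ymax)
        rows.append({
            "probe_id": pid,
            "kd_nM": est.kd,
            "kd_stderr_nM": est.kd_stderr,
            "ymax": est.ymax,
            "hill_n": est.hill_n,
            "model": est.model,
            "n_points": est.n_points,
            "converged": est.converged,
            "status": est.status,
        })
    return pd.DataFrame(rows)
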