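"""Trapping profiles and the SEM-weighted parabola fit.

A trapping profile plots the per-linker active fraction (mean +- SEM over
patches) against cross-linker span.  The profile is summarised by a parabola

    f(x) = K0 + K1 * (x - K2)**2

where K2 is the span (A) at which trapping is maximal (minimum active
fraction), K0 the minimum active fraction, and K1 the curvature.  The fit is
weighted least squares with weights 1/SEM^2, solved exactly in the quadratic
basis (a x^2 + b x + c) and converted to (K0, K1, K2):
K1 = a, K2 = -b / 2a, K0 = c - b^2 / 4a.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .linkers import CATALOG, CrossLinker, LinkerCatalog


@dataclass(frozen=True)
class ProfilePoint:
    span: float          # A
    mean: float          # active fraction
    sem: float
    n: int
    linker: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass
class ParabolaFit:
    K0: float            # minimum active fraction
    K1: float            # curvature (1/A^2)
    K2: float            # span at the minimum (A)
    uncertainties: dict
    weighted_sse: float
    flagged: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.K0 + self.K1 * (np.asarray(x, float) - self.K2) ** 2


def build_profile(measurements: Mapping[str, Sequence[float]],
                  catalog: LinkerCatalog = CATALOG,
                  include_monofunctional: bool = False) -> list[ProfilePoint]:
    """Aggregate per-patch active fractions into per-linker profile points.

    ``measurements`` maps linker name to the per-patch active fractions.
    Monofunctional reagents and unlinked ("w/o MTS") controls do not carry
    span semantics and are excluded from the fitted profile by default.
    SEM is the sample standard deviation over sqrt(n) (0 for n = 1).
    """
    if not measurements:
        raise ValueError("no measurements")
    points = []
    for name, values in measurements.items():
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise ValueError(f"no measurements for {name}")
        linker = catalog.get(name)
        if not linker.bifunctional and not include_monofunctional:
            continue
        sem = float(values.std(ddof=1) / np.sqrt(len(values))) \
            if len(values) > 1 else 0.0
        points.append(ProfilePoint(linker.span, float(values.mean()), sem,
                                   len(values), name))
    return sorted(points, key=lambda p: p.span)


def profile_frame(points: Iterable[ProfilePoint]) -> pd.DataFrame:
    return pd.DataFrame([{"linker": p.linker, "span_angstrom": p.span,
                          "mean": p.mean, "sem": p.sem, "n": p.n}
                         for p in points])


def read_profile_csv(path_or_buf) -> list[ProfilePoint]:
    """Read a profile table (columns linker, span_angstrom, mean, sem, n)."""
    df = pd.read_csv(path_or_buf)
    required = {"span_angstrom", "mean", "sem", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    return [ProfilePoint(float(row["span_angstrom"]), float(row["mean"]),
                         float(row["sem"]), int(row["n"]),
                         str(row.get("linker", "")))
            for _, row in df.iterrows()]


def fit_parabola(points: Sequence[ProfilePoint],
                 bounds: tuple[float, float] | None = None) -> ParabolaFit:
    """SEM-weighted least-squares parabola through profile points.

    Minimises sum(((y_i - f(x_i)) / sem_i)^2).  Points with sem = 0 are
    assigned the smallest nonzero SEM present (or 1 if all are zero) so that
    exact replicates do not get infinite weight.  The quadratic-basis normal
    equations are solved directly, making the fit deterministic; an inverted
    parabola (K1 <= 0) is flagged but still returned.  ``bounds`` optionally
    clamps K2 into a span range for ill-conditioned profiles.
    """
    x = np.array([p.span for p in points], dtype=float)
    y = np.array([p.mean for p in points], dtype=float)
    sem = np.array([p.sem for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 points with distinct spans")
    nonzero = sem[sem > 0]
    fill = nonzero.min() if nonzero.size else 1.0
    sem = np.where(sem > 0, sem, fill)
    w = 1.0 / sem**2

    # weighted normal equations in the (a, b, c) quadratic basis
    X = np.column_stack([x**2, x, np.ones_like(x)])
    A = X.T * w @ X
    rhs = X.T @ (w * y)
    a, b, c = np.linalg.solve(A, rhs)

    flag = ""
    if a <= 0:
        flag = "inverted parabola (K1 <= 0)"
        K1, K2 = a, (np.nan if a == 0 else -b / (2 * a))
        K0 = c if a == 0 else c - b**2 / (4 * a)
    else:
        K1 = a
        K2 = -b / (2 * a)
        K0 = c - b**2 / (4 * a)
        if bounds is not None:
            K2c = float(np.clip(K2, *bounds))
            if K2c != K2:
                # re-fit with the vertex pinned at the boundary
                K2 = K2c
                Xb = np.column_stack([(x - K2) ** 2, np.ones_like(x)])
                Ab = Xb.T * w @ Xb
                K1, K0 = np.linalg.solve(Ab, Xb.T @ (w * y))
                flag = "K2 at bounds"

    resid = y - (K0 + K1 * (x - K2) ** 2)
    sse = float(np.sum(w * resid**2))

    # parameter uncertainties from the weighted covariance in (a, b, c),
    # propagated linearly to (K0, K1, K2)
    try:
        cov_abc = np.linalg.inv(A)
        J = np.array([
            [b**2 / (4 * a**2), -b / (2 * a), 1.0],   # dK0/d(a,b,c)
            [1.0, 0.0, 0.0],                          # dK1
            [b / (2 * a**2), -1.0 / (2 * a), 0.0],    # dK2
        ]) if a != 0 else np.full((3, 3), np.nan)
        cov_k = J @ cov_abc @ J.T
        unc = {"K0": float(np.sqrt(abs(cov_k[0, 0]))),
               "K1": float(np.sqrt(abs(cov_k[1, 1]))),
               "K2": float(np.sqrt(abs(cov_k[2, 2])))}
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
        unc = {"K0": np.nan, "K1": np.nan, "K2": np.nan}

    return ParabolaFit(float(K0), float(K1), float(K2), unc, sse, flag)


def fit_report(fit: ParabolaFit) -> dict:
    return {"K0": fit.K0, "K1": fit.K1, "K2": fit.K2,
            "uncertainties": fit.uncertainties,
            "weighted_sse": fit.weighted_sse, "flagged": fit.flagged}
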