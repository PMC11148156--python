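"""Kinetic model fitting and screening-plate normalization.

Rate laws (rates in 1/s, concentrations in uM; unit conversion is the
caller's job):

  michaelis_menten      v = kcat * S / (K_M + S)
  substrate_inhibition  v = kcat * S / (K_M + S + S^2 / K_i)
  hill                  v = kcat * S^n / (K_half^n + S^n)

Fitting is nonlinear least squares (scipy's trust-region reflective,
positive parameter bounds) from a fixed, deterministic multi-start grid,
so identical data always yield identical fits.  Standard errors come
from the local curvature (the Jacobian-based covariance at the optimum).

Screening plates are normalized against on-plate controls:
score = (raw - mean blank) / (mean wildtype - mean blank), which is
invariant under affine transformation of the raw signal.  Wells at or
above a fold threshold are called as hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Raised when no start of the multi-start grid converges."""


@dataclass(frozen=True)
class RateLaw:
    """A registered kinetic rate law: v = f(S, *params)."""

    name: str
    func: Callable[..., np.ndarray]
    param_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _mm(s, kcat, km):
    return kcat * s / (km + s)


def _si(s, kcat, km, ki):
    return kcat * s / (km + s + s * s / ki)


def _hill(s, kcat, khalf, n):
    sn = np.power(s, n)
    return kcat * sn / (np.power(khalf, n) + sn)


RATE_LAWS: dict[str, RateLaw] = {
    "michaelis_menten": RateLaw("michaelis_menten", _mm, ("kcat", "K_M")),
    "substrate_inhibition": RateLaw("substrate_inhibition", _si, ("kcat", "K_M", "K_i")),
    "hill": RateLaw("hill", _hill, ("kcat", "K_half", "n")),
}


def register_rate_law(name: str, func: Callable[..., np.ndarray],
                      param_names: Sequence[str]) -> None:
    """Register an additional rate law for fitting."""
    if name in RATE_LAWS:
        raise ValueError(f"rate law {name!r} already registered")
    RATE_LAWS[name] = RateLaw(name, func, tuple(param_names))


@dataclass
class KineticDataset:
    """Paired substrate concentrations (uM) and observed rates (1/s)."""

    concentrations_uM: np.ndarray
    rates_per_s: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.rates_per_s = np.asarray(self.rates_per_s, dtype=float)
        if self.concentrations_uM.shape != self.rates_per_s.shape:
            raise ValueError("concentrations and rates must have equal length")
        if np.any(self.concentrations_uM < 0):
            raise ValueError("negative substrate concentration")
        if self.n_distinct < 4:
            raise ValueError(
                f"need >= 4 distinct concentrations for fitting, got {self.n_distinct}"
            )

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.concentrations_uM))

    @classmethod
    def from_csv(cls, path) -> "KineticDataset":
        """Columns: concentration_uM, rate_per_s, optional replicate."""
        frame = pd.read_csv(path)
        rep = frame["replicate"].to_numpy() if "replicate" in frame.columns else None
        return cls(frame["concentration_uM"].to_numpy(),
                   frame["rate_per_s"].to_numpy(), rep)


class KineticModel:
    """Nonlinear kinetic model bound to one dataset.

    ``KineticModel(data, "michaelis_menten").fit()`` returns a
    :class:`KineticFitResults` with parameter estimates, standard errors
    and residual diagnostics.
    """

    def __init__(self, data: KineticDataset, model: str = "michaelis_menten"):
        if model not in RATE_LAWS:
            raise ValueError(f"unknown model {model!r}; registered: {sorted(RATE_LAWS)}")
        self.data = data
        self.law = RATE_LAWS[model]
        if data.n_distinct < self.law.n_params + 1:
            raise ValueError(
                f"{model} has {self.law.n_params} parameters; need at least "
                f"{self.law.n_params + 1} distinct concentrations, got {data.n_distinct}"
            )

    def _starts(self) -> list[np.ndarray]:
        s = self.data.concentrations_uM
        v = self.data.rates_per_s
        km_starts = [float(np.min(s[s > 0])) if np.any(s > 0) else 1.0,
                     float(np.median(s)), float(np.max(s))]
        km_starts = [k if k > 0 else 1.0 for k in km_starts]
        kcat_starts = [float(np.max(v)), 1.5 * float(np.max(v))]
        kcat_starts = [k if k > 0 else 1.0 for k in kcat_starts]
        extra: list[float] = []
        if self.law.name == "substrate_inhibition":
            extra = [float(np.max(s))]
        elif self.law.name == "hill":
            extra = [1.0]
        elif self.law.n_params > 2:
            extra = [1.0] * (self.law.n_params - 2)
        starts = []
        for kc in kcat_starts:       # fixed order: kcat outer, K_M inner
            for km in km_starts:
                starts.append(np.array([kc, km, *extra]))
        return starts

    def fit(self) -> "KineticFitResults":
        s, v = self.data.concentrations_uM, self.data.rates_per_s
        best = None
        failures = []
        for p0 in self._starts():
            try:
                popt, pcov = curve_fit(
                    self.law.func, s, v, p0=p0,
                    bounds=(1e-12, np.inf), maxfev=20000, method="trf",
                )
            except (RuntimeError, ValueError) as exc:
                failures.append(f"start {p0}: {exc}")
                continue
            rss = float(np.sum((self.law.func(s, *popt) - v) ** 2))
            if best is None or rss < best[2] - 1e-15:
                best = (popt, pcov, rss)
        if best is None:
            raise FitError(
                f"no start converged for model {self.law.name!r}; attempts:\n"
                + "\n".join(failures)
            )
        popt, pcov, rss = best
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        return KineticFitResults(self, popt, perr, rss)


@dataclass
class KineticFitResults:
    """Fitted kinetic parameters with curvature-based standard errors."""

    model: KineticModel
    params: np.ndarray
    bse: np.ndarray
    rss: float
    param_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.param_names = self.model.law.param_names

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.bse[self.param_names.index(name)])

    def predict(self, concentrations_uM) -> np.ndarray:
        return self.model.law.func(np.asarray(concentrations_uM, dtype=float), *self.params)

    def gradient_norm(self) -> float:
        """Norm of the RSS gradient at the optimum (small when converged)."""
        s = self.model.data.concentrations_uM
        v = self.model.data.rates_per_s
        eps = 1e-6
        grad = []
        for k in range(len(self.params)):
            p_hi = self.params.copy(); p_hi[k] *= 1 + eps
            p_lo = self.params.copy(); p_lo[k] *= 1 - eps
            d = (np.sum((self.model.law.func(s, *p_hi) - v) ** 2)
                 - np.sum((self.model.law.func(s, *p_lo) - v) ** 2))
            grad.append(d / (2 * eps * self.params[k]))
        return float(np.linalg.norm(grad))

    def summary(self) -> str:
        lines = [
            f"Kinetic fit: {self.model.law.name}",
            "-" * 40,
            f"n points: {len(self.model.data.rates_per_s)}  "
            f"(distinct [S]: {self.model.data.n_distinct})",
        ]
        units = {"kcat": "1/s", "K_M": "uM", "K_i": "uM", "K_half": "uM", "n": ""}
        for name, value, err in zip(self.param_names, self.params, self.bse):
            u = units.get(name, "")
            lines.append(f"  {name:8s} = {value:10.4g} ± {err:.2g} {u}")
        lines.append(f"  RSS      = {self.rss:.4g}")
        return "\n".join(lines)


def fit_kinetics(data: KineticDataset, model: str = "michaelis_menten") -> KineticFitResults:
    """Convenience wrapper: ``KineticModel(data, model).fit()``."""
    return KineticModel(data, model).fit()


# ---------------------------------------------------------------------------
# screening plates


def normalize_screen(raw: pd.Series | np.ndarray,
                     roles: pd.Series | np.ndarray,
                     *, tol: float = 1e-9) -> pd.Series:
    """Normalize raw plate activities against on-plate controls.

    ``roles`` labels each well ``sample``, ``wildtype``, or ``blank``
    (at least two of each control).  The score of a well is
    (raw - mean blank) / (mean wildtype - mean blank): blanks average 0,
    wildtype wells average 1, and the score is invariant under affine
    rescaling of the raw signal.
    """
    raw = pd.Series(np.asarray(raw, dtype=float)) if not isinstance(raw, pd.Series) else raw.astype(float)
    roles = pd.Series(np.asarray(roles), index=raw.index) if not isinstance(roles, pd.Series) else roles
    valid = {"sample", "wildtype", "blank"}
    bad = set(roles.unique()) - valid
    if bad:
        raise ValueError(f"unknown well roles {sorted(bad)}; expected {sorted(valid)}")
    n_wt = int((roles == "wildtype").sum())
    n_blank = int((roles == "blank").sum())
    if n_wt < 2 or n_blank < 2:
        raise ValueError(
            f"need >= 2 wildtype and >= 2 blank wells, got {n_wt} and {n_blank}"
        )
    blank_mean = raw[roles == "blank"].mean()
    wt_mean = raw[roles == "wildtype"].mean()
    span = wt_mean - blank_mean
    if abs(span) < tol:
        raise ValueError(
            f"wildtype mean ({wt_mean:.3g}) indistinguishable from blank mean "
            f"({blank_mean:.3g}); cannot normalize"
        )
    return ((raw - blank_mean) / span).rename("score")


def read_plate_csv(path) -> tuple[pd.Series, pd.Series]:
    """Plate layout CSV with columns well, raw, role."""
    frame = pd.read_csv(path)
    frame = frame.set_index("well")
    return frame["raw"].astype(float), frame["role"]


def call_hits(scores: pd.Series, fold_threshold: float) -> pd.Series:
    """Wells scoring at or above ``fold_threshold``, best first.

    The threshold is a fold improvement over wildtype and must exceed 1.
    Ties are broken by well label for a fully deterministic order.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    hits = scores[scores >= fold_threshold]
    order = sorted(hits.index, key=lambda w: (-hits[w], str(w)))
    return hits.loc[order]
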