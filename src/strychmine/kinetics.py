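"""Michaelis-Menten steady-state fitting and catalytic-efficiency comparison.

The model is the standard steady-state initial-rate law

    v = kcat * E0 * S / (Km + S)

with kcat (min^-1) the turnover number, Km (uM) the Michaelis constant, E0
(uM) the enzyme concentration, and kcat/Km (min^-1 uM^-1) the catalytic
efficiency -- the second-order rate constant at limiting substrate, the
quantity on which substrate preferences of an enzyme are compared.

Fitting is unweighted nonlinear least squares on the raw velocities (an
optional 1/v^2 weighting mimics constant relative error).  Parameters are
optimized on the log scale, which enforces positivity; standard errors come
from the Jacobian at the optimum, mapped back to the natural scale by the
delta method.  Starting values come from the Hanes-Woolf linearization
(S/v regressed on S), which amplifies low-S noise far less than the
Lineweaver-Burk double reciprocal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import KineticsDataset


class MichaelisMenten:
    """Michaelis-Menten model of initial-rate data for one enzyme/substrate.

    Parameters
    ----------
    substrate_conc : substrate concentrations in uM (>= 4 distinct values).
    velocity : initial rates in uM/min, same length.
    enzyme_conc : total enzyme concentration E0 in uM.
    weights : "none" (default) for unweighted least squares, "relative" for
        1/v^2 weights (constant relative error).

    Examples
    --------
    >>> model = MichaelisMenten([1, 2, 5, 10, 20, 50],
    ...                         [0.033, 0.057, 0.1, 0.133, 0.16, 0.182], 0.1)
    >>> res = model.fit()
    >>> round(res.kcat, 2), round(res.km, 2)
    (2.0, 5.0)
    """

    def __init__(self, substrate_conc, velocity, enzyme_conc, weights="none"):
        s = np.asarray(substrate_conc, dtype=float)
        v = np.asarray(velocity, dtype=float)
        if s.ndim != 1 or s.shape != v.shape:
            raise ValueError("substrate_conc and velocity must be equal-length vectors")
        if np.unique(s).size < 4:
            raise ValueError("need at least 4 distinct substrate concentrations")
        if np.any(s <= 0) or np.any(v < 0):
            raise ValueError("substrate concentrations must be > 0, velocities >= 0")
        if enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be > 0")
        if weights not in ("none", "relative"):
            raise ValueError("weights must be 'none' or 'relative'")
        self.s = s
        self.v = v
        self.e0 = float(enzyme_conc)
        self.weights = weights

    @classmethod
    def from_dataset(cls, data: KineticsDataset, weights="none") -> "MichaelisMenten":
        return cls(data.substrate_conc, data.velocity, data.enzyme_conc, weights)

    @classmethod
    def from_tsv(cls, path: str | Path, weights="none") -> "MichaelisMenten":
        """Read a 3-column TSV (S_uM, v_uM_per_min, E_uM)."""
        df = pd.read_csv(path, sep="\t")
        e = df["E_uM"].unique()
        if len(e) != 1:
            raise ValueError("kinetics table must have a single enzyme concentration")
        return cls(df["S_uM"], df["v_uM_per_min"], float(e[0]), weights)

    # Hanes-Woolf: S/v = S/Vmax + Km/Vmax
    def _start_values(self) -> tuple[float, float]:
        mask = self.v > 0
        s, v = self.s[mask], self.v[mask]
        if s.size < 2:
            return 1.0, float(np.median(self.s))
        slope, intercept = np.polyfit(s, s / v, 1)
        if slope <= 0 or intercept <= 0:
            return float(self.v.max() / self.e0), float(np.median(self.s))
        vmax = 1.0 / slope
        km = intercept * vmax
        return vmax / self.e0, km

    def _model(self, kcat: float, km: float) -> np.ndarray:
        return kcat * self.e0 * self.s / (km + self.s)

    def fit(self) -> "MichaelisMentenResults":
        """Nonlinear least squares on (log kcat, log Km)."""
        w = 1.0 / np.maximum(self.v, np.finfo(float).tiny) if self.weights == "relative" else np.ones_like(self.v)

        def residuals(theta):
            kcat, km = np.exp(theta)
            return w * (self.v - self._model(kcat, km))

        kcat0, km0 = self._start_values()
        sol = optimize.least_squares(
            residuals, x0=np.log([max(kcat0, 1e-12), max(km0, 1e-12)]), method="lm"
        )
        kcat, km = np.exp(sol.x)
        rss = float(np.sum(sol.fun**2))
        dof = self.s.size - 2
        # covariance on the log scale from the Jacobian, then delta method
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = np.linalg.inv(jtj) * (rss / dof if dof > 0 else np.nan)
        except np.linalg.LinAlgError:
            cov_log = np.full((2, 2), np.nan)
        grad = np.diag([kcat, km])  # d(param)/d(log param) = param
        cov = grad @ cov_log @ grad
        converged = bool(sol.success and np.all(np.isfinite([kcat, km])))

        km_range = (self.s.min(), self.s.max())
        if converged and not (km_range[0] <= km <= km_range[1]):
            warnings.warn(
                f"fitted Km = {km:.3g} uM lies outside the assayed substrate range "
                f"{km_range}; the data poorly constrain the fit",
                stacklevel=2,
            )
        return MichaelisMentenResults(
            model=self,
            kcat=float(kcat),
            km=float(km),
            cov=cov,
            rss=rss,
            converged=converged,
            message=str(sol.message),
        )


@dataclass
class MichaelisMentenResults:
    """Fitted Michaelis-Menten parameters with uncertainties and diagnostics."""

    model: MichaelisMenten
    kcat: float
    km: float
    cov: np.ndarray  # 2x2 covariance of (kcat, km), natural scale
    rss: float
    converged: bool
    message: str = ""

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km in min^-1 uM^-1."""
        return self.kcat / self.km

    @property
    def bse(self) -> dict[str, float]:
        """Standard errors of kcat, Km and kcat/Km (delta method for the ratio)."""
        se_kcat = float(np.sqrt(self.cov[0, 0]))
        se_km = float(np.sqrt(self.cov[1, 1]))
        g = np.array([1.0 / self.km, -self.kcat / self.km**2])
        se_eff = float(np.sqrt(g @ self.cov @ g))
        return {"kcat": se_kcat, "km": se_km, "efficiency": se_eff}

    def predict(self, substrate_conc=None) -> np.ndarray:
        s = self.model.s if substrate_conc is None else np.asarray(substrate_conc, float)
        return self.kcat * self.model.e0 * s / (self.km + s)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Michaelis-Menten steady-state fit",
            "=" * 44,
            f"observations        : {self.model.s.size}",
            f"enzyme conc (uM)    : {self.model.e0:g}",
            f"kcat (min^-1)       : {self.kcat:.4g} (SE {se['kcat']:.2g})",
            f"Km (uM)             : {self.km:.4g} (SE {se['km']:.2g})",
            f"kcat/Km (min^-1 uM^-1): {self.efficiency:.4g} (SE {se['efficiency']:.2g})",
            f"residual SS         : {self.rss:.4g}",
            f"converged           : {self.converged}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        se = self.bse
        return {
            "kcat_per_min": self.kcat,
            "km_uM": self.km,
            "efficiency_per_min_per_uM": self.efficiency,
            "se_kcat": se["kcat"],
            "se_km": se["km"],
            "se_efficiency": se["efficiency"],
            "rss": self.rss,
            "converged": self.converged,
        }


def fit_mm(data: KineticsDataset, weights: str = "none") -> MichaelisMentenResults:
    """Convenience wrapper: build the model from a dataset and fit it."""
    return MichaelisMenten.from_dataset(data, weights=weights).fit()


def compare_efficiency(
    fit_a: MichaelisMentenResults, fit_b: MichaelisMentenResults
) -> dict:
    """Ratio of catalytic efficiencies (a over b) with a delta-method SE.

    For independent fits, (SE_R/R)^2 = (SE_a/eff_a)^2 + (SE_b/eff_b)^2.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged to compare efficiencies")
    ea, eb = fit_a.efficiency, fit_b.efficiency
    ratio = ea / eb
    rel = np.sqrt(
        (fit_a.bse["efficiency"] / ea) ** 2 + (fit_b.bse["efficiency"] / eb) ** 2
    )
    return {
        "efficiency_a": ea,
        "efficiency_b": eb,
        "ratio": ratio,
        "ratio_se": float(ratio * rel),
    }
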