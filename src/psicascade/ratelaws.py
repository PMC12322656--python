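"""Rate laws and ODE models of UMP hydrolysis and the one-pot cascade.

The nucleosidase (PpnN / its RY variant) hydrolyses UMP into uracil (Ura) and
ribose 5-phosphate (Rib5P); Rib5P is a competitive product inhibitor:

    v = Vmax·[UMP] / (Km·(1 + [Rib5P]/Ki) + [UMP]),   Vmax = kcat·[E]

The C-glycosidase YeiN condenses Rib5P and Ura into pseudouridine
5'-phosphate (ΨMP), modelled with an independent two-substrate saturation
form (the condensation direction is strongly favoured, so the model is
irreversible by default).  Coupling the two gives the one-pot cascade

    UMP → Ura + Rib5P → ΨMP + H2O

whose design rule — run YeiN in excess so it pulls Rib5P away from the
nucleosidase — is what the cascade simulator and the enzyme-ratio sweep
quantify.

For hydrolysis alone, the model admits a closed-form implicit solution

    t(S) = [Km·(1 + S0/Ki)·ln(S0/S) + (1 − Km/Ki)·(S0 − S)] / Vmax

which serves as an independent analytic check on the numerical integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidInputError
from .units import S_PER_MIN, EnzymeSpec, subunit_molarity

__all__ = [
    "KineticParams",
    "YeiNParams",
    "CascadeConfig",
    "ProgressCurve",
    "vmax_mM_per_min",
    "rate_eq1",
    "yein_rate",
    "calibrate_yein_kcat",
    "hydrolysis_time",
    "simulate_hydrolysis",
    "simulate_cascade",
    "enzyme_ratio_sweep",
]

# solver settings: late-phase product inhibition makes the system mildly
# stiff, so an implicit method with tight tolerances is the default
_RTOL = 1e-8
_ATOL = 1e-10
_METHOD = "Radau"

PROGRESS_COLUMNS = ["time_min", "UMP_mM", "Ura_mM", "Rib5P_mM", "PsiMP_mM"]


@dataclass(frozen=True)
class KineticParams:
    """Michaelis–Menten constants of the nucleosidase, with optional
    competitive product inhibition by Rib5P.

    kcat in s⁻¹, Km and Ki in mM.  ``ki=None`` means no inhibition term.
    """

    kcat: float
    km: float
    ki: float | None = None

    def __post_init__(self) -> None:
        if self.kcat < 0:
            raise InvalidInputError(f"kcat must be >= 0, got {self.kcat}")
        if self.km <= 0:
            raise InvalidInputError(f"Km must be > 0, got {self.km}")
        if self.ki is not None and self.ki <= 0:
            raise InvalidInputError(f"Ki must be > 0 when present, got {self.ki}")


@dataclass(frozen=True)
class YeiNParams:
    """Two-substrate saturation constants of the C-glycosidase.

    The rate law is v = Vmax·(R/(Km_R+R))·(U/(Km_U+U)) with R = Rib5P and
    U = Ura.  The published characterization reports only one operating
    point (7.0 U/mg at 15 mM of each substrate), so the default Km values
    of 1 mM are stated assumptions, not measurements, and the reverse
    (glycoside-cleaving) direction is omitted.
    """

    kcat: float
    km_rib5p: float = 1.0
    km_ura: float = 1.0
    reversible: bool = False

    def __post_init__(self) -> None:
        if self.kcat < 0 or self.km_rib5p <= 0 or self.km_ura <= 0:
            raise InvalidInputError("YeiN parameters must be positive")
        if self.reversible:
            raise InvalidInputError(
                "reversible YeiN kinetics are not modelled (condensation is "
                "strongly favoured); set reversible=False"
            )


@dataclass(frozen=True)
class CascadeConfig:
    """Configuration of a one-pot two-enzyme run."""

    ppnn_enzyme: EnzymeSpec
    ppnn_params: KineticParams
    yein_enzyme: EnzymeSpec
    yein_params: YeiNParams
    ump0: float
    t_end: float

    def __post_init__(self) -> None:
        if self.ump0 <= 0:
            raise InvalidInputError(f"initial UMP must be > 0, got {self.ump0}")
        if self.t_end <= 0:
            raise InvalidInputError(f"t_end must be > 0, got {self.t_end}")


@dataclass
class ProgressCurve:
    """Reaction time course: time grid (min) plus species concentrations (mM)."""

    time: np.ndarray
    ump: np.ndarray
    ura: np.ndarray
    rib5p: np.ndarray
    psimp: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ump = np.asarray(self.ump, dtype=float)
        self.ura = np.asarray(self.ura, dtype=float)
        self.rib5p = np.asarray(self.rib5p, dtype=float)
        if self.psimp is None:
            self.psimp = np.zeros_like(self.time)
        self.psimp = np.asarray(self.psimp, dtype=float)
        n = self.time.size
        for name in ("ump", "ura", "rib5p", "psimp"):
            if getattr(self, name).size != n:
                raise InvalidInputError(f"species {name} length != time grid length")

    def conversion(self, ump0: float | None = None) -> np.ndarray:
        """Fractional UMP conversion at each time point."""
        s0 = self.ump[0] if ump0 is None else ump0
        return 1.0 - self.ump / s0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(zip(PROGRESS_COLUMNS, [self.time, self.ump, self.ura, self.rib5p, self.psimp]))
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ProgressCurve":
        """Read the delimited time-course format; missing species columns are
        filled with zeros."""
        df = pd.read_csv(path)
        if "time_min" not in df.columns:
            raise InvalidInputError(f"{path}: missing required column 'time_min'")
        n = len(df)
        cols = {c: df[c].to_numpy(float) if c in df.columns else np.zeros(n)
                for c in PROGRESS_COLUMNS[1:]}
        return cls(df["time_min"].to_numpy(float), cols["UMP_mM"], cols["Ura_mM"],
                   cols["Rib5P_mM"], cols["PsiMP_mM"])


def vmax_mM_per_min(kcat: float, enzyme: EnzymeSpec) -> float:
    """Vmax = kcat·[E], converted to the internal mM/min scale."""
    return kcat * S_PER_MIN * subunit_molarity(enzyme)


def rate_eq1(
    params: KineticParams,
    enzyme: EnzymeSpec,
    substrate: float | np.ndarray,
    inhibitor: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Nucleosidase rate (mM/min) with competitive Rib5P inhibition.

    Reduces to plain Michaelis–Menten when ``params.ki`` is None or the
    inhibitor concentration is zero.  Vectorized over substrate/inhibitor.
    """
    s = np.asarray(substrate, dtype=float)
    i = np.asarray(inhibitor, dtype=float)
    if np.any(s < 0) or np.any(i < 0):
        raise InvalidInputError("concentrations must be >= 0")
    vmax = vmax_mM_per_min(params.kcat, enzyme)
    km_app = params.km * (1.0 + i / params.ki) if params.ki is not None else params.km * np.ones_like(i)
    out = vmax * s / (km_app + s)
    return float(out) if out.ndim == 0 else out


def yein_rate(
    params: YeiNParams,
    enzyme: EnzymeSpec,
    rib5p: float | np.ndarray,
    ura: float | np.ndarray,
) -> float | np.ndarray:
    """C-glycosidase condensation rate (mM/min), irreversible two-substrate
    saturation form."""
    r = np.asarray(rib5p, dtype=float)
    u = np.asarray(ura, dtype=float)
    if np.any(r < 0) or np.any(u < 0):
        raise InvalidInputError("concentrations must be >= 0")
    vmax = vmax_mM_per_min(params.kcat, enzyme)
    out = vmax * (r / (params.km_rib5p + r)) * (u / (params.km_ura + u))
    return float(out) if out.ndim == 0 else out


def calibrate_yein_kcat(
    specific_activity: float = 7.0,
    enzyme_molar_mass: float = 32909.0,
    km_rib5p: float = 1.0,
    km_ura: float = 1.0,
    anchor_conc: float = 15.0,
) -> float:
    """kcat (s⁻¹) such that the rate law reproduces the measured specific
    activity at the assay's anchor point (15 mM of each substrate)."""
    kcat_observed = specific_activity * enzyme_molar_mass / (S_PER_MIN * 1000.0)
    saturation = (anchor_conc / (km_rib5p + anchor_conc)) * (anchor_conc / (km_ura + anchor_conc))
    return kcat_observed / saturation


def hydrolysis_time(
    substrate: float | np.ndarray,
    s0: float,
    vmax: float,
    km: float,
    ki: float | None = None,
) -> float | np.ndarray:
    """Closed-form implicit solution t(S) of product-inhibited hydrolysis.

    With competitive product inhibition (product P = S0 − S acting on Km):

        t(S) = [Km·(1 + S0/Ki)·ln(S0/S) + (1 − Km/Ki)·(S0 − S)] / Vmax

    With ``ki=None`` this degenerates to the integrated Michaelis–Menten
    relation Km·ln(S0/S) + (S0 − S) = Vmax·t.  Time in minutes for Vmax in
    mM/min.
    """
    s = np.asarray(substrate, dtype=float)
    if np.any(s <= 0) or np.any(s > s0):
        raise InvalidInputError("substrate must lie in (0, S0]")
    if ki is None:
        t = (km * np.log(s0 / s) + (s0 - s)) / vmax
    else:
        t = (km * (1.0 + s0 / ki) * np.log(s0 / s) + (1.0 - km / ki) * (s0 - s)) / vmax
    return float(t) if t.ndim == 0 else t


def _check_grid(t_grid: Sequence[float]) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidInputError("time grid must be 1-D with at least two points")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("time grid must increase strictly from 0")
    return t


def _solve(rhs, y0, t: np.ndarray, label: str):
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, method=_METHOD, rtol=_RTOL, atol=_ATOL,
                    t_eval=t, dense_output=True)
    if not sol.success:
        raise IntegrationError(f"{label}: solver failed: {sol.message}")
    return sol


def simulate_hydrolysis(
    enzyme: EnzymeSpec,
    params: KineticParams,
    s0: float,
    t_grid: Sequence[float],
) -> ProgressCurve:
    """Integrate dS/dt = −v(S, P) with P = S0 − S for single-enzyme UMP
    hydrolysis; mass balance gives Ura = Rib5P = S0 − S at every point."""
    if s0 <= 0:
        raise InvalidInputError(f"S0 must be > 0, got {s0}")
    t = _check_grid(t_grid)

    def rhs(_t, y):
        s = max(y[0], 0.0)
        return [-rate_eq1(params, enzyme, s, s0 - s)]

    sol = _solve(rhs, [s0], t, "hydrolysis")
    s = np.clip(sol.y[0], 0.0, s0)
    released = s0 - s
    return ProgressCurve(t, s, released.copy(), released.copy(), np.zeros_like(t))


def simulate_cascade(cfg: CascadeConfig, t_grid: Sequence[float] | None = None) -> ProgressCurve:
    """Integrate the coupled two-enzyme system.

    States: UMP, Rib5P, Ura, ΨMP with
        d[UMP]/dt  = −v1        d[Rib5P]/dt = v1 − v2
        d[Ura]/dt  = v1 − v2    d[ΨMP]/dt   = v2
    where v1 is the Rib5P-inhibited nucleosidase rate and v2 the YeiN
    condensation rate.  Two mass balances hold along the trajectory:
    UMP + Ura + ΨMP = UMP₀ and UMP + Rib5P + ΨMP = UMP₀.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, cfg.t_end, 201)
    t = _check_grid(t_grid)

    def rhs(_t, y):
        ump, rib5p, ura = (max(v, 0.0) for v in y[:3])
        v1 = rate_eq1(cfg.ppnn_params, cfg.ppnn_enzyme, ump, rib5p)
        v2 = yein_rate(cfg.yein_params, cfg.yein_enzyme, rib5p, ura)
        return [-v1, v1 - v2, v1 - v2, v2]

    sol = _solve(rhs, [cfg.ump0, 0.0, 0.0, 0.0], t, "cascade")
    y = np.clip(sol.y, 0.0, None)
    return ProgressCurve(t, y[0], y[2], y[1], y[3])


def enzyme_ratio_sweep(
    total_protein: float,
    ratios: Sequence[float],
    cfg_template: CascadeConfig,
    t_eval: float,
) -> pd.DataFrame:
    """UMP conversion at ``t_eval`` for each YeiN:PpnN mass-ratio split at
    constant total protein loading.

    ``ratios`` are YeiN/PpnN mass ratios (e.g. 2.0 means YeiN in twofold
    mass excess).  Returns a frame with columns ``ratio``, ``ppnn_g_per_L``,
    ``yein_g_per_L``, ``conversion``.
    """
    if len(ratios) == 0:
        raise InvalidInputError("ratio list must not be empty")
    if total_protein <= 0:
        raise InvalidInputError("total protein loading must be > 0")
    if any(r < 0 for r in ratios):
        raise InvalidInputError("ratios must be >= 0")
    rows = []
    for r in ratios:
        ppnn_load = total_protein / (1.0 + r)
        yein_load = total_protein - ppnn_load
        cfg = CascadeConfig(
            cfg_template.ppnn_enzyme.with_mass_conc(ppnn_load),
            cfg_template.ppnn_params,
            cfg_template.yein_enzyme.with_mass_conc(yein_load),
            cfg_template.yein_params,
            cfg_template.ump0,
            max(cfg_template.t_end, t_eval),
        )
        t = np.linspace(0.0, t_eval, 101)
        curve = simulate_cascade(cfg, t)
        rows.append((r, ppnn_load, yein_load, float(curve.conversion()[-1])))
    return pd.DataFrame(rows, columns=["ratio", "ppnn_g_per_L", "yein_g_per_L", "conversion"])
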