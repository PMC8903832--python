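"""Model parameters and pointwise physics of chemotactic front migration.

The model couples a nutrient/attractant field ``c`` (L-serine, in uM) and a
bacterial number-density field ``b`` (cells/um^3) through

    dc/dt = Dc * lap(c) - b * kappa * g(c)
    db/dt = -div(Jb) + b * gamma * g(c),      Jb = -Db grad(b) + b chi grad(f(c))

with Michaelis-Menten kinetics ``g(c) = c/(c + c_half)`` and logarithmic
nutrient sensing ``f(c) = log[(1 + c/c_minus)/(1 + c/c_plus)]``.  The motility
coefficients ``Db`` and ``chi`` are per-medium constants reduced at high cell
density by a crowding correction (see :func:`motility_correction`).

All quantities are kept in a single internal unit system:

    length  um, time  s, concentration  uM, cell density  cells/um^3.

Literature values quoted in other units (mM, cells/mL, min, hr) are converted
once, at parameter construction, and round-trip conversions are exposed for
testing.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParams",
    "PorousMediumParams",
    "MEDIUM_PRESETS",
    "medium_preset",
    "monod_g",
    "sensing_f",
    "sensing_fprime",
    "mean_cell_separation",
    "motility_correction",
    "reaction_terms",
    "scale_estimates",
]

# unit conversion constants
MM_TO_UM = 1.0e3  # mM -> uM
CELLS_PER_ML_TO_PER_UM3 = 1.0e-12  # cells/mL -> cells/um^3
# kappa printed as mM (cell/mL)^-1 s^-1; internally uM um^3 cell^-1 s^-1:
# multiply by 1e3 (mM->uM) and by 1e12 (per cell/mL -> per cell/um^3).
KAPPA_PRINTED_TO_INTERNAL = MM_TO_UM / CELLS_PER_ML_TO_PER_UM3  # 1e15: 1.6e-11 printed -> 1.6e4 internal

SECONDS_PER_HOUR = 3600.0


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass(frozen=True)
class PorousMediumParams:
    """Motility preset for one porous medium.

    Attributes
    ----------
    xi : float
        Mean pore size in um.  Metadata only; the dynamics see only the
        four derived quantities below.
    Db0 : float
        Cellular diffusivity of a dilute population, um^2/s.
    chi0 : float
        Chemotactic coefficient, um^2/s.
    f_pore : float
        Pore-space volume fraction (dimensionless, in (0, 1)).
    l_c : float
        Mean chord length of the pore space, um.
    """

    xi: float
    Db0: float
    chi0: float
    f_pore: float
    l_c: float

    def __post_init__(self) -> None:
        if not (self.Db0 >= 0 and self.chi0 >= 0):
            raise ParameterError("motility coefficients must be nonnegative")
        if not (0.0 < self.f_pore < 1.0):
            raise ParameterError("f_pore must lie in (0, 1)")
        if self.l_c <= 0 or self.xi <= 0:
            raise ParameterError("lengths must be positive")

    def with_coefficients(self, Db0: float | None = None,
                          chi0: float | None = None) -> "PorousMediumParams":
        """Copy with replaced motility coefficients (used by knockouts and
        chi calibration)."""
        return dataclasses.replace(
            self,
            Db0=self.Db0 if Db0 is None else Db0,
            chi0=self.chi0 if chi0 is None else chi0,
        )


#: Measured presets for the three experimental media, keyed by mean pore
#: size label in um: (xi, Db0 [um^2/s], chi0 [um^2/s], f_pore, l_c [um]).
MEDIUM_PRESETS: dict[float, PorousMediumParams] = {
    2.2: PorousMediumParams(xi=2.2, Db0=2.32, chi0=145.0, f_pore=0.36, l_c=4.6),
    1.7: PorousMediumParams(xi=1.7, Db0=0.93, chi0=9.0, f_pore=0.17, l_c=3.1),
    1.2: PorousMediumParams(xi=1.2, Db0=0.42, chi0=5.0, f_pore=0.04, l_c=2.4),
}


def medium_preset(xi: float) -> PorousMediumParams:
    """Return the motility preset for mean pore size ``xi`` (1.2/1.7/2.2 um)."""
    try:
        return MEDIUM_PRESETS[float(xi)]
    except KeyError:
        raise ParameterError(
            f"no preset for xi={xi}; available: {sorted(MEDIUM_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ModelParams:
    """Biochemical and biophysical constants of the continuum model.

    Defaults reproduce the measured/literature values for *E. coli*
    migrating toward L-serine; internal units are um / s / uM / cells/um^3.

    Attributes
    ----------
    Dc : float
        Nutrient diffusivity, um^2/s.
    kappa : float
        Maximal consumption rate per cell, uM um^3 cell^-1 s^-1.  The
        literature value is quoted as 1.6e-11 mM (cell/mL)^-1 s^-1, which
        converts to 1.6e4 in internal units.
    c_half : float
        Michaelis-Menten half-saturation concentration, uM.
    gamma : float
        Maximal proliferation rate, 1/s (default ln2 per hour).
    c_minus, c_plus : float
        Lower and upper receptor dissociation constants of the sensing
        function, uM; sensing saturates above ``c_plus``.
    d_cell : float
        Characteristic cell size entering the crowding correction, um.
    b_pack : float
        Packed inoculum density, cells/um^3 (0.95 corresponds to the
        printed 0.95e12 cells/mL).
    c0 : float
        Initial nutrient concentration, uM (1e4 uM = 10 mM).
    sensing_mode : str
        ``"logarithmic"`` (saturating) or ``"linear"`` (non-saturating
        control variant ``f(c) = c/c_lin``).
    tau_delay : float
        Delay before starvation-induced signal loss begins, s.
    tau_starve : float
        Signal decay constant after nutrient depletion, s (1782 s = 29.7 min).
    c_star : float
        Nutrient threshold of the starvation-signal model, uM.  The natural
        kinetic scale ``c_half`` is used by default; configurable.
    knockout_diffusion, knockout_growth, knockout_chemotaxis : bool
        Flags that zero Db, gamma, or chi exactly (mechanism knockouts).
    """

    Dc: float = 800.0
    kappa: float = 1.6e-11 * KAPPA_PRINTED_TO_INTERNAL
    c_half: float = 1.0
    gamma: float = math.log(2.0) / SECONDS_PER_HOUR
    c_minus: float = 1.0
    c_plus: float = 30.0
    d_cell: float = 1.0
    b_pack: float = 0.95
    c0: float = 1.0e4
    sensing_mode: str = "logarithmic"
    tau_delay: float = 7200.0
    tau_starve: float = 1782.0
    c_star: float = 1.0
    knockout_diffusion: bool = False
    knockout_growth: bool = False
    knockout_chemotaxis: bool = False

    def __post_init__(self) -> None:
        for name in ("Dc", "kappa", "c_half", "gamma", "c_minus", "c_plus",
                     "d_cell", "b_pack", "c0", "tau_delay", "tau_starve",
                     "c_star"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and nonnegative")
            if v <= 0 and name not in ("c0",):
                raise ParameterError(f"{name} must be strictly positive")
        if not self.c_minus < self.c_plus:
            raise ParameterError("require c_minus < c_plus")
        if self.sensing_mode not in ("logarithmic", "linear"):
            raise ParameterError("sensing_mode must be 'logarithmic' or 'linear'")

    # -- derived quantities -------------------------------------------------

    @property
    def c_lin(self) -> float:
        """Scale of the linear sensing variant: (1/c_minus - 1/c_plus)^-1 (uM).

        Chosen so that ``c/c_lin`` matches the logarithmic ``f`` at small c.
        """
        return 1.0 / (1.0 / self.c_minus - 1.0 / self.c_plus)

    @property
    def gamma_eff(self) -> float:
        """Proliferation rate after applying the growth knockout."""
        return 0.0 if self.knockout_growth else self.gamma

    @property
    def kappa_printed(self) -> float:
        """kappa converted back to the printed units, mM (cell/mL)^-1 s^-1."""
        return self.kappa / KAPPA_PRINTED_TO_INTERNAL

    def effective_medium(self, medium: PorousMediumParams) -> PorousMediumParams:
        """Apply the knockout flags to a medium's motility coefficients."""
        return medium.with_coefficients(
            Db0=0.0 if self.knockout_diffusion else None,
            chi0=0.0 if self.knockout_chemotaxis else None,
        )

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# pointwise physics
# ---------------------------------------------------------------------------

def _check_nonneg(c, name: str = "c") -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def monod_g(c, params: ModelParams):
    """Michaelis-Menten nutrient-availability factor g(c) = c/(c + c_half).

    Dimensionless, in [0, 1); monotone increasing; g(c_half) = 1/2.
    """
    c = _check_nonneg(c)
    out = c / (c + params.c_half)
    return out if out.ndim else float(out)


def sensing_f(c, params: ModelParams):
    """Sensed signal f(c).

    Logarithmic mode (default): ``log[(1 + c/c_minus)/(1 + c/c_plus)]``
    (natural log) -- linear in c below ``c_minus``, saturating at
    ``log(c_plus/c_minus)`` above ``c_plus``.  Linear mode: ``c/c_lin``
    with the same small-c slope but no saturation.
    """
    c = _check_nonneg(c)
    if params.sensing_mode == "linear":
        out = c / params.c_lin
    else:
        out = np.log1p(c / params.c_minus) - np.log1p(c / params.c_plus)
    return out if out.ndim else float(out)


def sensing_fprime(c, params: ModelParams):
    """Chemotactic response factor f'(c) (analytic derivative, 1/uM).

    Logarithmic mode: ``1/(c + c_minus) - 1/(c + c_plus)``, strictly
    positive and strictly decreasing (receptor saturation).  Linear mode:
    the constant ``1/c_lin``.
    """
    c = _check_nonneg(c)
    if params.sensing_mode == "linear":
        out = np.full_like(c, 1.0 / params.c_lin)
    else:
        out = 1.0 / (c + params.c_minus) - 1.0 / (c + params.c_plus)
    return out if out.ndim else float(out)


def mean_cell_separation(b, medium: PorousMediumParams, params: ModelParams):
    """Mean surface separation between cells, ``(3 f_pore/(4 pi b))^(1/3) - d``.

    Monotone decreasing in the local density ``b``; negative when cells
    overlap (jamming).  Non-positive ``b`` returns +inf (no crowding).
    """
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore"):
        l = np.where(
            b > 0.0,
            np.cbrt(3.0 * medium.f_pore / (4.0 * math.pi * np.maximum(b, 1e-300)))
            - params.d_cell,
            np.inf,
        )
    return l if l.ndim else float(l)


def motility_correction(b, medium: PorousMediumParams, params: ModelParams):
    """Density-dependent motility factor applied to both Db and chi.

    Cell-cell collisions truncate the random-walk step length once the mean
    cell separation ``l_cell`` falls below the mean chord length ``l_c`` of
    the pore space; the factor is ``(l_cell/l_c)^2`` there, 1 for dilute
    populations, and exactly 0 once cells are jammed (``l_cell <= 0``).
    """
    b = np.asarray(np.maximum(b, 0.0), dtype=float)
    l = mean_cell_separation(np.maximum(b, 1e-300), medium, params)
    l = np.asarray(l, dtype=float)
    frac = np.clip(l / medium.l_c, 0.0, 1.0)
    out = np.where(l >= medium.l_c, 1.0, frac * frac)
    return out if out.ndim else float(out)


def reaction_terms(state, params: ModelParams, medium: PorousMediumParams | None = None):
    """Pointwise source terms of the model: (consumption, growth).

    ``state`` is any object with ``b`` and ``c`` array attributes (or a
    ``(b, c)`` pair).  Returns ``(-b*kappa*g(c), +b*gamma*g(c))`` -- the
    nutrient sink and the cell-proliferation source.  The growth knockout
    zeroes the second term exactly.
    """
    if hasattr(state, "b"):
        b, c = state.b, state.c
    else:
        b, c = state
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if b.shape != c.shape:
        raise ValueError(f"field shape mismatch: b {b.shape} vs c {c.shape}")
    g = monod_g(c, params)
    consumption = -params.kappa * b * g
    growth = params.gamma_eff * b * g
    return consumption, growth


def scale_estimates(lambda_: float, Db: float, gamma: float, A0: float,
                    l_cell_body: float) -> tuple[float, float]:
    """Back-of-envelope smoothing time scales for competing mechanisms, in hours.

    Returns ``(lambda^2 / Db, gamma^-1 * log2(A0 / l_cell_body))``: the time
    for undirected diffusion to smooth an undulation of wavelength
    ``lambda_`` and the shortest time for cells of body length
    ``l_cell_body`` growing end-to-end at rate ``gamma`` to span ``A0``.
    Both are orders of magnitude longer than the observed smoothing, which
    is why chemotaxis must drive it.
    """
    for name, v in (("lambda_", lambda_), ("Db", Db), ("gamma", gamma),
                    ("A0", A0), ("l_cell_body", l_cell_body)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if A0 <= l_cell_body:
        raise ValueError("A0 must exceed the cell body length")
    t_diff = lambda_**2 / Db / SECONDS_PER_HOUR
    t_grow = math.log2(A0 / l_cell_body) / gamma / SECONDS_PER_HOUR
    return t_diff, t_grow


# ---------------------------------------------------------------------------
# TOML (de)serialization of parameter presets
# ---------------------------------------------------------------------------

def params_to_toml(params: ModelParams, medium: PorousMediumParams | None = None) -> str:
    """Serialize parameters (and optionally a medium preset) to TOML text."""
    def emit(name: str, obj) -> Iterable[str]:
        yield f"[{name}]"
        for f_ in dataclasses.fields(obj):
            v = getattr(obj, f_.name)
            if isinstance(v, bool):
                yield f"{f_.name} = {'true' if v else 'false'}"
            elif isinstance(v, str):
                yield f'{f_.name} = "{v}"'
            else:
                yield f"{f_.name} = {float(v)!r}"
    lines = list(emit("model", params))
    if medium is not None:
        lines += [""] + list(emit("medium", medium))
    return "\n".join(lines) + "\n"


def params_from_toml(text: str) -> tuple[ModelParams, PorousMediumParams | None]:
    """Inverse of :func:`params_to_toml`."""
    import tomllib

    doc = tomllib.loads(text)
    params = ModelParams(**doc["model"])
    medium = PorousMediumParams(**doc["medium"]) if "medium" in doc else None
    return params, medium
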