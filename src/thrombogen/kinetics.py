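"""Per-individual simulation of thrombin generation.

Builds a nanomolar initial state from an individual's measured plasma factor
panel, integrates the mass-action system with a stiff solver (analytic
Jacobian generated from the reaction list) and reports every species plus the
total-active-thrombin trace on a uniform 1 s grid over 20 minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelDefinition, stoichiometry_matrix

__all__ = [
    "PlasmaComposition",
    "SimulationConfig",
    "ThrombinWeights",
    "TimeCourse",
    "CompositionWarning",
    "CompositionRangeWarning",
    "SimulationError",
    "EXCLUSION_FLAGS",
    "FACTOR_SPECIES",
    "initial_state",
    "mass_action_rhs",
    "simulate",
    "total_thrombin_trace",
]

# exclusion categories from the study's inclusion criteria
EXCLUSION_FLAGS = (
    "coumadin",
    "unknown_coumadin",
    "unconfirmed_thrombosis",
    "superficial_only",
    "insufficient_sample",
    "insufficient_composition",
)

# (composition attribute, model species, scale to nM)
FACTOR_SPECIES = (
    ("fII_uM", "II", 1000.0),
    ("fV_nM", "V", 1.0),
    ("fVII_nM", "VII", 1.0),
    ("fVIII_nM", "VIII", 1.0),
    ("fIX_nM", "IX", 1.0),
    ("fX_nM", "X", 1.0),
    ("AT_uM", "AT", 1000.0),
    ("TFPI_nM", "TFPI", 1.0),
    ("PC_nM", "PC", 1.0),
)

# clinically accepted normal range and observed kindred range, input units
_NORMAL_RANGE = {
    "fII_uM": (0.8, 2.0),
    "fV_nM": (12.0, 28.0),
    "fVII_nM": (6.0, 14.0),
    "fVIII_nM": (0.4, 1.6),
    "fIX_nM": (62.0, 135.0),
    "fX_nM": (96.0, 224.0),
    "AT_uM": (3.2, 6.3),
    "TFPI_nM": (1.1, 4.3),
    "PC_nM": (50.0, 119.0),
}
_OBSERVED_RANGE = {
    "fII_uM": (0.7, 2.9),
    "fV_nM": (7.0, 60.0),
    "fVII_nM": (4.0, 20.5),
    "fVIII_nM": (0.24, 1.8),
    "fIX_nM": (47.6, 225.0),
    "fX_nM": (79.8, 274.0),
    "AT_uM": (1.5, 5.6),
    "TFPI_nM": (1.1, 5.0),
    "PC_nM": (16.0, 207.0),
}


class CompositionWarning(UserWarning):
    """Factor level outside the clinically accepted normal range."""


class CompositionRangeWarning(CompositionWarning):
    """Factor level outside even the observed kindred range."""


class SimulationError(RuntimeError):
    pass


@dataclass
class PlasmaComposition:
    """Measured plasma factor panel plus covariates and group labels."""

    subject_id: str
    fII_uM: float
    fV_nM: float
    fVII_nM: float
    fVIII_nM: float
    fIX_nM: float
    fX_nM: float
    AT_uM: float
    TFPI_nM: float
    PC_nM: float
    sex: str = "F"
    age: float = 45.0
    pc_mutation: str = "no"
    pt_g20210a: str = "no"
    thrombosis_history: str = "none"
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for attr, _, _ in FACTOR_SPECIES:
            v = getattr(self, attr)
            # zero is tolerated so that knockout-style control experiments
            # (e.g. PC=0, TFPI=0) can be expressed; negatives are rejected
            if not (v >= 0) or not np.isfinite(v):
                raise ValueError(f"{self.subject_id}: {attr} must be a nonnegative finite number, got {v}")
        unknown = set(self.exclusions) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(f"{self.subject_id}: unknown exclusion flags {sorted(unknown)}")

    def validate_ranges(self) -> None:
        """Warn on out-of-range values; never reject (they are still simulated)."""
        for attr, _, _ in FACTOR_SPECIES:
            v = getattr(self, attr)
            lo, hi = _OBSERVED_RANGE[attr]
            if not (lo <= v <= hi):
                warnings.warn(
                    f"{self.subject_id}: {attr}={v} outside observed kindred range [{lo}, {hi}]",
                    CompositionRangeWarning,
                    stacklevel=2,
                )
                continue
            lo, hi = _NORMAL_RANGE[attr]
            if not (lo <= v <= hi):
                warnings.warn(
                    f"{self.subject_id}: {attr}={v} outside accepted normal range [{lo}, {hi}]",
                    CompositionWarning,
                    stacklevel=2,
                )


#: physiologic mean factor levels, used for the mean physiologic control
#: and for percent-of-mean conversion.
PHYSIOLOGIC_MEAN = PlasmaComposition(
    subject_id="physiologic_control",
    fII_uM=1.4,
    fV_nM=20.0,
    fVII_nM=10.0,
    fVIII_nM=0.7,
    fIX_nM=90.0,
    fX_nM=160.0,
    AT_uM=3.6,
    TFPI_nM=2.5,
    PC_nM=65.0,
)


@dataclass(frozen=True)
class ThrombinWeights:
    w_iia: float = 1.0
    w_miia: float = 1.2
    include_tm_bound: bool = False

    def __post_init__(self) -> None:
        if self.w_iia < 0 or self.w_miia < 0:
            raise ValueError("thrombin weights must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    tf_trigger_pM: float = 5.0
    tm_nM: float = 1.0
    duration_s: float = 1200.0
    report_interval_s: float = 1.0
    include_pc: bool = True
    fviia_fraction: float = 0.01
    thrombin_weights: ThrombinWeights = field(default_factory=ThrombinWeights)
    rtol: float = 1e-8
    atol: float = 1e-12
    max_conservation_drift: float = 1e-3

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")
        n = self.duration_s / self.report_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be divisible by report_interval")
        if not (0 <= self.fviia_fraction < 1):
            raise ValueError("fviia_fraction must be in [0, 1)")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.duration_s / self.report_interval_s))
        return np.linspace(0.0, self.duration_s, n + 1)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Flat ``key = value`` file mirroring the config fields.

        Thrombin weights use the keys ``w_iia``, ``w_miia`` and
        ``include_tm_bound``; booleans are ``true``/``false``.
        """
        from pathlib import Path

        scalars: dict[str, object] = {}
        weights: dict[str, object] = {}
        bool_keys = {"include_pc", "include_tm_bound"}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (part.strip() for part in line.split("=", 1))
            value: object
            if key in bool_keys:
                if raw.lower() not in ("true", "false"):
                    raise ValueError(f"{path}:{lineno}: {key} must be true/false")
                value = raw.lower() == "true"
            else:
                value = float(raw)
            if key in ("w_iia", "w_miia", "include_tm_bound"):
                weights[key] = value
            elif key in cls.__dataclass_fields__ and key != "thrombin_weights":
                scalars[key] = value
            else:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if weights:
            scalars["thrombin_weights"] = ThrombinWeights(**weights)  # type: ignore[arg-type]
        return cls(**scalars)  # type: ignore[arg-type]


@dataclass
class TimeCourse:
    time: np.ndarray                    # s
    species: tuple[str, ...]
    concentrations: np.ndarray          # (time, species) nM, clamped >= 0
    thrombin: np.ndarray                # total active thrombin, nM
    diagnostics: dict

    def trace(self, symbol: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(symbol)]


def initial_state(
    model: ModelDefinition, composition: PlasmaComposition, config: SimulationConfig
) -> np.ndarray:
    """Initial nanomolar state: zymogens/inhibitors at plasma levels, TF trigger,
    thrombomodulin at its set level, a small fVIIa fraction, everything else 0."""
    idx = model.species_index()
    y0 = np.zeros(len(model.species))
    for attr, symbol, scale in FACTOR_SPECIES:
        if symbol not in idx:
            continue  # e.g. no PC in the base submodel, reduced toy models
        y0[idx[symbol]] = getattr(composition, attr) * scale
    viia = composition.fVII_nM * config.fviia_fraction
    if viia > 0 and "VIIa" in idx:
        y0[idx["VIIa"]] = viia
        y0[idx["VII"]] -= viia
    if "TF" in idx:
        y0[idx["TF"]] = config.tf_trigger_pM / 1000.0
    elif config.tf_trigger_pM > 0:
        raise ValueError("model has no TF species but a nonzero trigger was requested")
    if "Tm" in idx:
        y0[idx["Tm"]] = config.tm_nM
    elif config.tm_nM > 0 and config.include_pc:
        raise ValueError("model has no Tm species but a nonzero Tm level was requested")
    return y0


class _MassAction:
    """Vectorized RHS and dense Jacobian generated from the reaction list."""

    def __init__(self, model: ModelDefinition):
        self.N = stoichiometry_matrix(model).astype(float)
        idx = model.species_index()
        n_rxn = len(model.reactions)
        self.k = np.empty(n_rxn)
        self.i1 = np.empty(n_rxn, dtype=int)
        self.i2 = np.full(n_rxn, -1, dtype=int)
        for j, rxn in enumerate(model.reactions):
            self.k[j] = model.rate_constants[rxn.rate_constant_id].value
            mols = [idx[sym] for sym, c in rxn.reactants for _ in range(c)]
            self.i1[j] = mols[0]
            if len(mols) == 2:
                self.i2[j] = mols[1]
        self.bimol = self.i2 >= 0

    def flux(self, y: np.ndarray) -> np.ndarray:
        v = self.k * y[self.i1]
        v[self.bimol] *= y[self.i2[self.bimol]]
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.N @ self.flux(y)

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        n_rxn, n_sp = len(self.k), self.N.shape[0]
        dv = np.zeros((n_rxn, n_sp))
        rows = np.arange(n_rxn)
        uni = ~self.bimol
        dv[rows[uni], self.i1[uni]] = self.k[uni]
        b = rows[self.bimol]
        i1b, i2b = self.i1[self.bimol], self.i2[self.bimol]
        kb = self.k[self.bimol]
        np.add.at(dv, (b, i1b), kb * y[i2b])
        np.add.at(dv, (b, i2b), kb * y[i1b])
        return self.N @ dv


_RHS_CACHE: dict[int, _MassAction] = {}


def _mass_action(model: ModelDefinition) -> _MassAction:
    key = id(model)
    if key not in _RHS_CACHE:
        _RHS_CACHE[key] = _MassAction(model)
    return _RHS_CACHE[key]


def mass_action_rhs(model: ModelDefinition, state: np.ndarray) -> np.ndarray:
    """d[state]/dt in nM/s under mass action; N @ flux by construction."""
    state = np.asarray(state, dtype=float)
    if state.shape != (len(model.species),):
        raise ValueError(f"state length {state.shape} != species count {len(model.species)}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains NaN/Inf")
    return _mass_action(model).rhs(0.0, state)


def simulate(
    model: ModelDefinition,
    composition: PlasmaComposition,
    config: SimulationConfig = SimulationConfig(),
) -> TimeCourse:
    """Integrate the stiff system over the full window and report on the 1 s grid."""
    ma = _mass_action(model)
    y0 = initial_state(model, composition, config)
    grid = config.grid
    sol = solve_ivp(
        ma.rhs,
        (0.0, config.duration_s),
        y0,
        method="LSODA",
        t_eval=grid,
        jac=ma.jac,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        stiffest = model.species_symbols[int(np.argmax(np.abs(ma.rhs(0.0, sol.y[:, -1]))))]
        raise SimulationError(
            f"{composition.subject_id}: integrator failed ({sol.message}); "
            f"stiffest flux at species {stiffest!r}"
        )
    conc = sol.y.T.copy()

    # audit moiety conservation on the raw (unclamped) solution
    M = model.moiety_matrix().astype(float)
    totals = conc @ M.T  # (time, moieties)
    t0 = totals[0]
    scale = np.where(t0 > 0, t0, 1.0)
    drift = np.abs(totals - t0) / scale
    max_drift = float(drift.max()) if drift.size else 0.0
    if max_drift > config.max_conservation_drift:
        worst = model.moiety_names()[int(np.argmax(drift.max(axis=0)))]
        raise SimulationError(
            f"{composition.subject_id}: conservation drift {max_drift:.2e} on moiety "
            f"{worst!r} exceeds {config.max_conservation_drift:.0e}; tighten solver tolerances"
        )

    np.clip(conc, 0.0, None, out=conc)
    diagnostics = {
        "nfev": int(sol.nfev),
        "njev": int(sol.njev),
        "nlu": int(sol.nlu),
        "max_conservation_drift": max_drift,
    }
    tc = TimeCourse(grid, model.species_symbols, conc, np.zeros(len(grid)), diagnostics)
    tc.thrombin = total_thrombin_trace(tc, config.thrombin_weights)
    return tc


def total_thrombin_trace(tc: TimeCourse, weights: ThrombinWeights = ThrombinWeights()) -> np.ndarray:
    """Weighted sum of active thrombin species: w_IIa*[IIa] + w_mIIa*[mIIa]
    (plus Tm-bound forms when enabled)."""
    wanted: list[tuple[str, float]] = [("IIa", weights.w_iia), ("mIIa", weights.w_miia)]
    if weights.include_tm_bound:
        wanted += [("IIa=Tm", weights.w_iia), ("mIIa=Tm", weights.w_miia)]
    out = np.zeros(len(tc.time))
    for sym, w in wanted:
        if sym not in tc.species:
            warnings.warn(f"species {sym!r} absent from submodel; weight ignored", stacklevel=2)
            continue
        out += w * tc.trace(sym)
    return out
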