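"""Synthetic factorial greenhouse-experiment generator.

Real gas-exchange campaigns of this kind sweep a full factorial of chamber
conditions — here 6 leaf temperatures x 4 CO2 concentrations x 13 light
intensities, three replicate plants per combination (312 combinations, 936
records) — and log, per record, the net photosynthetic rate ``Pn`` together
with the chlorophyll-fluorescence parameters qP, ETR, PhiPS2, Fv'/Fm', NPQ
and qN.  This module generates datasets with the same design and with
response surfaces shaped like measured cucumber light-response curves:

* ``Pn`` over light follows a rectangular hyperbola with a ``(1 - beta*I)``
  photoinhibition factor, peaking near the cucumber light-saturation point of
  ~990 umol m-2 s-1, modulated by a Gaussian temperature optimum and a
  Michaelis-Menten CO2 response.
* ``PhiPS2`` decays with light; ``ETR = PhiPS2 * PAR * absorptance * f_PSII``
  rises then falls; ``NPQ`` saturates with light and declines beyond a
  photodamage threshold; qP and Fv'/Fm' are tied to PhiPS2.

Replicate plants differ by multiplicative Gaussian noise.  Sustained
quenching qN is modelled as a near-constant leaf property dominated by
plant-to-plant variability, so that it carries almost no information about
``Pn`` — mirroring the non-significant qN correlation seen in measured data.

At zero light the fluorescence parameters are undefined (no actinic
excitation), so records with ``par == 0`` carry ``valid_fluor = False`` and
NaN fluorescence values.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SchemaError

SCHEMA_VERSION = 1

#: column order of the on-disk CSV and of Dataset.frame
COLUMNS = [
    "tem", "co2", "par", "rh",
    "pn", "qp", "etr", "phips2", "fvpfmp", "npq", "qn",
    "valid_fluor",
]

FLUOR_COLUMNS = ["qp", "etr", "phips2", "fvpfmp", "npq", "qn"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PnSurfaceParams:
    """Parameters of the noise-free net-photosynthesis surface.

    The surface is ``Pn = alpha*I*(1-beta*I)/(1+gamma*I) * g(T) * h(C) - r_d``
    with ``g(T) = exp(-((T-t_opt)/t_sigma)^2)`` and ``h(C) = C/(C+k_c)``.
    Defaults are calibrated so the light optimum sits at ~990 umol m-2 s-1
    (the optimum of the light factor is independent of T and C because the
    surface is separable).
    """

    alpha: float = 0.12        # initial slope, umol CO2 per umol photons
    beta: float = 2.0e-4       # photoinhibition coefficient, per umol m-2 s-1
    gamma: float = 3.081e-3    # saturation coefficient, per umol m-2 s-1
    t_opt: float = 28.0        # optimal temperature, degC
    t_sigma: float = 10.0      # temperature breadth, degC
    k_c: float = 300.0         # CO2 half-saturation, umol mol-1
    r_d: float = 0.8           # dark respiration, umol m-2 s-1

    def validate(self) -> None:
        if not (self.alpha > 0 and self.gamma > 0 and self.beta >= 0):
            raise ConfigurationError("alpha>0, gamma>0, beta>=0 required")
        if not (self.t_sigma > 0 and self.k_c > 0 and self.r_d >= 0):
            raise ConfigurationError("t_sigma>0, k_c>0, r_d>=0 required")


@dataclass(frozen=True)
class FluorSurfaceParams:
    """Parameters of the noise-free chlorophyll-fluorescence surfaces."""

    phi0: float = 0.75             # maximal PSII yield at low light
    i_phi: float = 900.0           # PhiPS2 decay scale, umol m-2 s-1
    leaf_absorptance: float = 0.84
    psii_fraction: float = 0.5     # fraction of absorbed light to PSII
    npq_max: float = 2.5           # asymptotic NPQ
    npq_k: float = 400.0           # NPQ half-saturation light, umol m-2 s-1
    npq_h: float = 1.5             # NPQ Hill exponent
    i_damage: float = 1000.0       # light beyond which NPQ declines
    damage_slope: float = 5.0e-4   # NPQ decline per umol m-2 s-1 past i_damage
    fvpfmp0: float = 0.82          # Fv'/Fm' scale
    fvpfmp_q: float = 0.6          # exponent tying Fv'/Fm' to PhiPS2, in (0,1)
    qn_coupling: float = 0.01      # weight of record-level NPQ in qN
    qn_jitter_sd: float = 0.05     # plant-to-plant qN variability (sd)

    def validate(self) -> None:
        if not 0 < self.phi0 < 1:
            raise ConfigurationError("phi0 must lie in (0,1)")
        if not 0 < self.leaf_absorptance <= 1:
            raise ConfigurationError("leaf_absorptance must lie in (0,1]")
        if not 0 < self.psii_fraction <= 1:
            raise ConfigurationError("psii_fraction must lie in (0,1]")
        if not self.npq_max > 0:
            raise ConfigurationError("npq_max must be positive")
        if not 0 < self.fvpfmp_q < 1:
            raise ConfigurationError("fvpfmp_q must lie in (0,1)")


DEFAULT_TEMP_LEVELS = (18.0, 20.0, 24.0, 28.0, 32.0, 36.0)
DEFAULT_CO2_LEVELS = (300.0, 600.0, 900.0, 1200.0)
DEFAULT_PAR_LEVELS = (20.0, 50.0, 100.0, 200.0, 300.0, 500.0, 700.0,
                      900.0, 1000.0, 1100.0, 1200.0, 1300.0, 1500.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Factorial design plus noise model of one synthetic campaign."""

    temp_levels: tuple[float, ...] = DEFAULT_TEMP_LEVELS
    co2_levels: tuple[float, ...] = DEFAULT_CO2_LEVELS
    par_levels: tuple[float, ...] = DEFAULT_PAR_LEVELS
    rh: float = 50.0
    replicates: int = 3
    noise_cv: float = 0.03
    seed: int = 0
    surface_params: PnSurfaceParams = field(default_factory=PnSurfaceParams)
    fluor_params: FluorSurfaceParams = field(default_factory=FluorSurfaceParams)

    def __post_init__(self):
        object.__setattr__(self, "temp_levels", tuple(float(v) for v in self.temp_levels))
        object.__setattr__(self, "co2_levels", tuple(float(v) for v in self.co2_levels))
        object.__setattr__(self, "par_levels", tuple(float(v) for v in self.par_levels))
        self.validate()

    def validate(self) -> None:
        for name, levels in (("temp_levels", self.temp_levels),
                             ("co2_levels", self.co2_levels),
                             ("par_levels", self.par_levels)):
            if len(levels) == 0:
                raise ConfigurationError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ConfigurationError(f"{name} must be strictly increasing")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        self.surface_params.validate()
        self.fluor_params.validate()

    def grid_size(self) -> int:
        return len(self.temp_levels) * len(self.co2_levels) * len(self.par_levels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "surface_params" in d and isinstance(d["surface_params"], dict):
            d["surface_params"] = PnSurfaceParams(**d["surface_params"])
        if "fluor_params" in d and isinstance(d["fluor_params"], dict):
            d["fluor_params"] = FluorSurfaceParams(**d["fluor_params"])
        return cls(**d)


@dataclass(frozen=True)
class SampleRecord:
    """One measurement row: chamber conditions, Pn, fluorescence parameters."""

    tem: float
    co2: float
    par: float
    rh: float
    pn: float
    qp: float
    etr: float
    phips2: float
    fvpfmp: float
    npq: float
    qn: float
    valid_fluor: bool


@dataclass
class Dataset:
    """Ordered measurement records plus provenance metadata.

    ``frame`` holds the records as a :class:`pandas.DataFrame` with columns
    :data:`COLUMNS`; ``meta`` echoes the generator configuration, seed and
    schema version (empty for datasets read from unannotated files).
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[SampleRecord]:
        return [SampleRecord(**{k: (bool(v) if k == "valid_fluor" else float(v))
                                for k, v in row.items()})
                for row in self.frame[COLUMNS].to_dict("records")]


# ---------------------------------------------------------------------------
# deterministic response surfaces
# ---------------------------------------------------------------------------

def build_factorial_grid(config: GeneratorConfig) -> list[tuple[float, float, float]]:
    """Full Cartesian product of (temperature, CO2, light) levels.

    Deterministic nested order: temperature outermost, CO2 middle, light
    innermost, so downstream splits are reproducible.
    """
    config.validate()
    return [(t, c, p)
            for t in config.temp_levels
            for c in config.co2_levels
            for p in config.par_levels]


def pn_surface(tem, co2, par, params: PnSurfaceParams | None = None):
    """Noise-free net photosynthetic rate (umol CO2 m-2 s-1).

    Modified rectangular hyperbola in light with a linear photoinhibition
    term, times a Gaussian temperature-optimum factor and a Michaelis-Menten
    CO2 factor, minus dark respiration.  Accepts scalars or arrays.
    """
    if params is None:
        params = PnSurfaceParams()
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise DomainError("par must be >= 0")
    tem = np.asarray(tem, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    light = params.alpha * par * (1.0 - params.beta * par) / (1.0 + params.gamma * par)
    temp = np.exp(-(((tem - params.t_opt) / params.t_sigma) ** 2))
    carbon = co2 / (co2 + params.k_c)
    out = light * temp * carbon - params.r_d
    return out if out.ndim else float(out)


def _modulation(tem, co2):
    # mild environmental modulation of PhiPS2, kept within [0.92, 1.08]
    # for the factorial ranges 18-36 degC and 300-1200 umol mol-1
    return 1.0 + 0.04 * (tem - 27.0) / 9.0 + 0.04 * (co2 - 750.0) / 450.0


def fluorescence_surface(tem, co2, par, params: FluorSurfaceParams | None = None):
    """Noise-free fluorescence parameters ``(qp, etr, phips2, fvpfmp, npq, qn)``.

    PhiPS2 decays exponentially with light (scale ``i_phi``) under a mild
    temperature/CO2 modulation; ETR is the standard product
    ``PhiPS2 * PAR * absorptance * f_PSII``; Fv'/Fm' follows PhiPS2 through a
    concave power law (so Fv'/Fm' >= PhiPS2); qP is their ratio; NPQ is a Hill
    saturation in light damped past the photodamage threshold; the noise-free
    qN is the conventional ``1 - exp(-NPQ)`` transform.

    Requires ``par > 0``: at zero light the parameters are undefined.
    """
    if params is None:
        params = FluorSurfaceParams()
    par = np.asarray(par, dtype=float)
    if np.any(par <= 0):
        raise DomainError("fluorescence parameters require par > 0")
    tem = np.asarray(tem, dtype=float)
    co2 = np.asarray(co2, dtype=float)

    phips2 = params.phi0 * np.exp(-par / params.i_phi) * _modulation(tem, co2)
    etr = phips2 * par * params.leaf_absorptance * params.psii_fraction
    fvpfmp = params.fvpfmp0 * (phips2 / params.phi0) ** params.fvpfmp_q
    qp = np.clip(phips2 / fvpfmp, None, 1.0)
    hill = par ** params.npq_h / (par ** params.npq_h + params.npq_k ** params.npq_h)
    damage = np.maximum(0.0, 1.0 - params.damage_slope * np.maximum(0.0, par - params.i_damage))
    npq = params.npq_max * hill * damage
    qn = 1.0 - np.exp(-npq)
    if np.ndim(qp):
        return qp, etr, phips2, fvpfmp, npq, qn
    return tuple(float(v) for v in (qp, etr, phips2, fvpfmp, npq, qn))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig | None = None) -> Dataset:
    """Generate one replicated factorial campaign.

    Each observed quantity is the surface value times ``(1 + eps)`` with
    ``eps ~ Normal(0, noise_cv)`` drawn per record and per quantity from a
    generator seeded by ``config.seed``; record invariants (qP and yields in
    [0,1], non-negative ETR/NPQ) are enforced by clipping after noise.  qN is
    dominated by an independent per-plant jitter (sd ``qn_jitter_sd``) around
    the mid-range sustained-quenching level, with only a weak
    (``qn_coupling``) contribution from the record's own NPQ.  With
    ``noise_cv == 0`` generation is fully deterministic and replicate rows
    within a group are identical.
    """
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = build_factorial_grid(config)
    fp = config.fluor_params

    tem = np.repeat([g[0] for g in grid], config.replicates)
    co2 = np.repeat([g[1] for g in grid], config.replicates)
    par = np.repeat([g[2] for g in grid], config.replicates)
    n = tem.size

    pn = pn_surface(tem, co2, par, config.surface_params)
    valid = par > 0

    qp = np.full(n, np.nan)
    etr = np.full(n, np.nan)
    phips2 = np.full(n, np.nan)
    fvpfmp = np.full(n, np.nan)
    npq = np.full(n, np.nan)
    qn = np.full(n, np.nan)
    if valid.any():
        (qp[valid], etr[valid], phips2[valid],
         fvpfmp[valid], npq[valid], _) = fluorescence_surface(
            tem[valid], co2[valid], par[valid], fp)

    if config.noise_cv > 0:
        def jitter(values):
            return values * (1.0 + rng.normal(0.0, config.noise_cv, size=n))
        pn = jitter(pn)
        qp = jitter(qp)
        etr = jitter(etr)
        phips2 = jitter(phips2)
        fvpfmp = jitter(fvpfmp)
        npq = jitter(npq)
        qn_noise = rng.normal(0.0, fp.qn_jitter_sd, size=n)
    else:
        qn_noise = np.zeros(n)

    # qN: sustained quenching around a mid-range reference NPQ level, nearly
    # decoupled from the record-level NPQ (hence from Pn)
    npq_ref = 0.5 * fp.npq_max
    qn_arg = (1.0 - fp.qn_coupling) * npq_ref + fp.qn_coupling * np.where(valid, npq, npq_ref)
    qn = np.where(valid, 1.0 - np.exp(-qn_arg) + qn_noise, np.nan)

    # enforce record invariants by clipping after noise
    etr = np.maximum(etr, 0.0)
    npq = np.maximum(npq, 0.0)
    fvpfmp = np.clip(fvpfmp, 0.0, 1.0)
    phips2 = np.clip(phips2, 0.0, fvpfmp)
    qp = np.clip(qp, 0.0, 1.0)
    qn = np.clip(qn, 0.0, 1.0)

    frame = pd.DataFrame({
        "tem": tem, "co2": co2, "par": par,
        "rh": np.full(n, float(config.rh)),
        "pn": pn, "qp": qp, "etr": etr, "phips2": phips2,
        "fvpfmp": fvpfmp, "npq": npq, "qn": qn,
        "valid_fluor": valid,
    })
    meta = {"schema_version": SCHEMA_VERSION,
            "seed": config.seed,
            "config": config.to_dict()}
    return Dataset(frame=frame, meta=meta)


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset to CSV with a '#'-prefixed metadata header.

    Numeric fields are written with 17 significant digits so a read/write
    round trip reproduces them to at least 12 significant digits.
    """
    path = Path(path)
    buf = io.StringIO()
    meta = dict(dataset.meta)
    meta.setdefault("schema_version", SCHEMA_VERSION)
    buf.write("# photonet dataset\n")
    buf.write("# meta: " + json.dumps(meta, default=float) + "\n")
    dataset.frame.to_csv(buf, index=False, float_format="%.17g",
                         columns=COLUMNS)
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_dataset(path) -> Dataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    Raises :class:`SchemaError` naming the offending column or row when the
    file has missing/extra columns or non-numeric cells.
    """
    path = Path(path)
    meta: dict = {}
    with path.open(encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("# meta:"):
            try:
                meta = json.loads(line[len("# meta:"):])
            except json.JSONDecodeError as exc:
                raise SchemaError(f"unparseable metadata header: {exc}") from exc
    try:
        frame = pd.read_csv(io.StringIO(text), comment="#")
    except Exception as exc:  # malformed CSV body
        raise SchemaError(f"unreadable CSV body: {exc}") from exc

    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s): {', '.join(extra)}")

    for col in COLUMNS:
        if col == "valid_fluor":
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"non-numeric value in column '{col}', row {row}")
        frame[col] = coerced.astype(float)
    frame["valid_fluor"] = frame["valid_fluor"].astype(bool)
    return Dataset(frame=frame[COLUMNS], meta=meta)
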