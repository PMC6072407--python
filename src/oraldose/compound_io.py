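"""Input/output for compound tables and simulation settings.

A :class:`Compound` bundles the measured physicochemical and pharmacokinetic
inputs needed to simulate oral dosing of one drug: ionization (charge type and
pKa), aqueous solubility at pH 7.4, apparent Caco2 permeability (A->B) at
pH 6.5, steady-state volume of distribution, plasma clearance, optional plasma
protein binding and the molecular weight used to convert molar solubility to
mass.  :class:`ModelSettings` holds every fixed constant of the simulation
protocol (intestinal geometry, dosing schedule, dose grid, error model).

The packaged reference table (``data/reference_compounds.csv``) carries the
15 well-characterised oral drugs used throughout the documentation and tests.
Molecular weights are standard monograph values for the free acid/base.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "Compound",
    "ModelSettings",
    "CompoundValidationError",
    "SettingsError",
    "read_compounds",
    "write_compounds",
    "load_settings",
    "load_reference_compounds",
    "reference_compounds_path",
    "DEFAULT_DOSES_MG",
]

CHARGE_TYPES = ("neutral", "monoacid", "monobase")

#: The 20 oral doses (mg) of the default simulation protocol.
DEFAULT_DOSES_MG: tuple[float, ...] = (
    0.000001, 0.000005, 0.00001, 0.00005, 0.0001, 0.001, 0.01, 0.1,
    1.0, 10.0, 25.0, 50.0, 75.0, 100.0, 250.0, 500.0, 1000.0, 2500.0,
    5000.0, 10000.0,
)

_COMPOUND_COLUMNS = (
    "name",
    "charge_type",
    "pka",
    "solubility_ph74",
    "papp_caco2_ph65",
    "vss_per_kg",
    "cl_per_kg",
    "ppb_percent_bound",
    "mol_weight",
)

_MANDATORY_COLUMNS = tuple(c for c in _COMPOUND_COLUMNS if c not in ("pka", "ppb_percent_bound"))


class CompoundValidationError(ValueError):
    """A compound record violates the input-data contract."""


class SettingsError(ValueError):
    """A settings file contains unknown keys or non-physical values."""


@dataclass(frozen=True)
class Compound:
    """One drug's input record.

    Parameters
    ----------
    name : str
        Compound identifier.
    charge_type : {"neutral", "monoacid", "monobase"}
        Ionization class at physiological pH; multiprotic species and
        zwitterions are not supported.
    pka : float or None
        Single ionization constant; required unless ``charge_type`` is
        ``"neutral"`` (and must be absent when it is).
    solubility_ph74 : float
        Aqueous solubility at pH 7.4 and room temperature (mol L^-1).
    papp_caco2_ph65 : float
        Apparent Caco2 permeability, apical-to-basolateral, at pH 6.5
        (cm s^-1).
    vss_per_kg : float
        Human volume of distribution at steady state (L kg^-1).
    cl_per_kg : float
        Human plasma clearance (mL min^-1 kg^-1).
    ppb_percent_bound : float or None
        Plasma protein binding (% bound, in [0, 100)).  When absent, free
        (unbound) quantity levels cannot be computed for the compound.
    mol_weight : float
        Molecular weight (g mol^-1); converts molar solubility to mg.
    """

    name: str
    charge_type: str
    pka: float | None
    solubility_ph74: float
    papp_caco2_ph65: float
    vss_per_kg: float
    cl_per_kg: float
    ppb_percent_bound: float | None
    mol_weight: float

    def __post_init__(self) -> None:
        if self.charge_type not in CHARGE_TYPES:
            raise CompoundValidationError(
                f"{self.name}: unsupported charge_type {self.charge_type!r}; "
                f"expected one of {CHARGE_TYPES}"
            )
        if (self.pka is None) != (self.charge_type == "neutral"):
            raise CompoundValidationError(
                f"{self.name}: pKa must be present exactly when charge_type is "
                f"monoacid/monobase (got charge_type={self.charge_type!r}, pka={self.pka!r})"
            )
        for attr in ("solubility_ph74", "papp_caco2_ph65", "vss_per_kg", "mol_weight"):
            value = getattr(self, attr)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise CompoundValidationError(f"{self.name}: {attr} must be a positive number, got {value!r}")
        if not (math.isfinite(self.cl_per_kg) and self.cl_per_kg >= 0):
            raise CompoundValidationError(f"{self.name}: cl_per_kg must be >= 0, got {self.cl_per_kg!r}")
        if self.ppb_percent_bound is not None and not (0 <= self.ppb_percent_bound < 100):
            raise CompoundValidationError(
                f"{self.name}: ppb_percent_bound must lie in [0, 100), got {self.ppb_percent_bound!r}"
            )

    @property
    def fraction_unbound(self) -> float | None:
        """(100 - % bound)/100, or ``None`` when binding is unknown."""
        if self.ppb_percent_bound is None:
            return None
        return (100.0 - self.ppb_percent_bound) / 100.0

    def replace(self, **changes) -> "Compound":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ModelSettings:
    """Fixed constants of the repeat-dose simulation protocol.

    The defaults encode the standard protocol: a 0.08 L cylindrical
    intestinal segment of radius 1.25 cm with a surface-amplification factor
    of 2, a 1 h gastric lag followed by a 4 h absorption window, 14 doses
    12 h apart (168 h total), a 70 kg subject with 1450 mL min^-1 liver
    blood flow, and a 20-point dose grid from 1 ng to 10 g.
    """

    v_intestinal: float = 0.08          # L
    intestinal_radius: float = 1.25     # cm
    absorption_amplification: float = 2.0
    gastric_lag: float = 60.0           # min
    absorption_window: float = 240.0    # min
    dose_interval: float = 720.0        # min
    n_doses: int = 14
    sim_length: float | None = None     # min; defaults to n_doses * dose_interval
    body_weight: float = 70.0           # kg
    q_h: float = 1450.0                 # mL min^-1, hepatic blood flow
    dose_list: tuple[float, ...] = DEFAULT_DOSES_MG
    grid_step: float = 15.0             # min
    n_random_timepoints: int = 336
    rng_seed: int = 20180205
    slope_tolerance: float = 1e-4
    error_sd_log10: float = 0.3
    n_error_scenarios: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_list", tuple(float(d) for d in self.dose_list))
        if self.sim_length is None:
            object.__setattr__(self, "sim_length", self.n_doses * self.dose_interval)
        positive = (
            "v_intestinal", "intestinal_radius", "absorption_amplification",
            "absorption_window", "dose_interval", "sim_length", "body_weight",
            "q_h", "grid_step", "slope_tolerance",
        )
        for attr in positive:
            if not getattr(self, attr) > 0:
                raise SettingsError(f"{attr} must be > 0, got {getattr(self, attr)!r}")
        if self.gastric_lag < 0:
            raise SettingsError(f"gastric_lag must be >= 0, got {self.gastric_lag!r}")
        if self.n_doses < 1:
            raise SettingsError(f"n_doses must be >= 1, got {self.n_doses!r}")
        if self.error_sd_log10 < 0:
            raise SettingsError(f"error_sd_log10 must be >= 0, got {self.error_sd_log10!r}")
        if self.n_error_scenarios < 0:
            raise SettingsError(f"n_error_scenarios must be >= 0, got {self.n_error_scenarios!r}")
        if self.n_random_timepoints < 0:
            raise SettingsError(f"n_random_timepoints must be >= 0")
        if any(d < 0 for d in self.dose_list):
            raise SettingsError("doses must be >= 0")
        if self.sim_length < (self.n_doses - 1) * self.dose_interval + self.gastric_lag + self.absorption_window:
            raise SettingsError(
                "sim_length must cover the absorption window of the final dose"
            )

    @property
    def t_end(self) -> float:
        return self.sim_length

    @property
    def dose_times(self) -> tuple[float, ...]:
        """Dose administration times t_i = (i-1) * dose_interval (min)."""
        return tuple(i * self.dose_interval for i in range(self.n_doses))

    @property
    def cl_units_to_l_per_min(self) -> float:
        """Factor converting mL min^-1 kg^-1 to whole-body L min^-1."""
        return self.body_weight / 1000.0

    def replace(self, **changes) -> "ModelSettings":
        return dataclasses.replace(self, **changes)


def _parse_optional(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_compounds(path: str | Path) -> list[Compound]:
    """Read a compound table from CSV.

    The file must carry a header naming at least the mandatory columns
    (``name, charge_type, solubility_ph74, papp_caco2_ph65, vss_per_kg,
    cl_per_kg, mol_weight``); ``pka`` and ``ppb_percent_bound`` may be blank.
    Scientific notation is accepted.  Raises :class:`CompoundValidationError`
    naming the offending column or row on schema/validation failure.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"name": str, "charge_type": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise CompoundValidationError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    compounds: list[Compound] = []
    for idx, row in frame.iterrows():
        try:
            compounds.append(
                Compound(
                    name=str(row["name"]).strip(),
                    charge_type=str(row["charge_type"]).strip().lower(),
                    pka=_parse_optional(row.get("pka")),
                    solubility_ph74=float(row["solubility_ph74"]),
                    papp_caco2_ph65=float(row["papp_caco2_ph65"]),
                    vss_per_kg=float(row["vss_per_kg"]),
                    cl_per_kg=float(row["cl_per_kg"]),
                    ppb_percent_bound=_parse_optional(row.get("ppb_percent_bound")),
                    mol_weight=float(row["mol_weight"]),
                )
            )
        except CompoundValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise CompoundValidationError(f"{path}: row {idx + 1}: {exc}") from exc
    return compounds


def write_compounds(compounds: Sequence[Compound], path: str | Path) -> None:
    """Write compounds to CSV with full float precision (round-trip safe)."""
    frame = pd.DataFrame([dataclasses.asdict(c) for c in compounds], columns=list(_COMPOUND_COLUMNS))
    frame.to_csv(path, index=False)


def load_settings(path: str | Path | None = None, **overrides) -> ModelSettings:
    """Load :class:`ModelSettings` from a YAML/JSON file, or defaults.

    ``path=None`` returns the default protocol.  Keys in the file (and any
    keyword overrides) must be valid :class:`ModelSettings` fields; unknown
    keys raise :class:`SettingsError`.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise SettingsError(f"{path}: expected a mapping of settings keys")
        data.update(loaded)
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(ModelSettings)}
    unknown = set(data) - valid
    if unknown:
        raise SettingsError(f"unknown settings key(s): {', '.join(sorted(unknown))}")
    return ModelSettings(**data)


def reference_compounds_path() -> Path:
    """Filesystem path of the packaged 15-compound reference table."""
    return Path(resources.files("oraldose").joinpath("data/reference_compounds.csv"))


def load_reference_compounds() -> list[Compound]:
    """Load the packaged 15-compound reference table."""
    return read_compounds(reference_compounds_path())
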