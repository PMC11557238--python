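"""Run configuration: a single TOML file with one block per stage.

All physics defaults live in the bundled, versioned data files; the config
names them explicitly so every parameter gap the model fills is visible
and editable.  Parameter ranges outside the studied bounds are allowed but
emit warnings.
"""

from __future__ import annotations

import hashlib
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .registry import Registry, default_registry, load_registry
from .tracks import DEFAULT_INITIAL_YIELDS, TrackParams

__all__ = ["RunConfig", "load_config", "default_config_toml"]

STUDIED_TAU = (1e-13, 1e-6)
STUDIED_ENERGY = (1e4, 1e6)
STUDIED_N_ELECTRONS = (1, 100)


@dataclass
class RunConfig:
    """Validated configuration for simulate / sweep / fit / validate runs."""

    # pulse block
    n_electrons: int = 10
    pulse_duration_s: float = 1e-12
    energy_ev: float = 1e4
    beam_fwhm_m: float = 5e-6
    envelope: str = "tophat"
    # track block
    spur_energy_min_ev: float = 17.0
    spur_energy_max_ev: float = 100.0
    cutoff_energy_ev: float = 500.0
    sigma_heavy_m: float = 2.0e-9
    sigma_electron_m: float = 5.0e-9
    pc_offset_s: float = 1e-12
    max_spurs: int | None = None
    initial_yields: dict = field(default_factory=lambda: dict(DEFAULT_INITIAL_YIELDS))
    # chemistry block
    species_table: str | None = None
    reaction_table: str | None = None
    debye: bool = False
    o2_concentration_m: float = 0.0
    t_end_rule: str = "pulse_end"
    window_s: float = 1e-6
    cutoff_factor: float = 10.0
    r_cut_max_m: float = 3e-7
    # sweep block
    tau_grid_s: tuple = tuple(10.0 ** -k for k in range(13, 5, -1))
    replicates: int = 8
    sweep_species: tuple = ("OH", "e_aq", "H2O2", "H3O+")
    # run block
    seed: int = 1
    output_dir: str = "pulsechem_out"
    log_level: str = "info"
    config_hash: str = ""

    def registry(self) -> Registry:
        if self.species_table or self.reaction_table:
            if not (self.species_table and self.reaction_table):
                raise ConfigError(
                    "species_table and reaction_table must be given together"
                )
            reg = load_registry(self.species_table, self.reaction_table, debye=self.debye)
            return reg.with_scavenger("O2", self.o2_concentration_m) if "O2" in reg.index else reg
        return default_registry(debye=self.debye, o2_concentration=self.o2_concentration_m)

    def track_params(self) -> TrackParams:
        return TrackParams(
            kinetic_energy=self.energy_ev,
            spur_energy_range=(self.spur_energy_min_ev, self.spur_energy_max_ev),
            cutoff_energy=self.cutoff_energy_ev,
            initial_yields=dict(self.initial_yields),
            sigma_heavy=self.sigma_heavy_m,
            sigma_electron=self.sigma_electron_m,
            pc_offset=self.pc_offset_s,
            max_spurs=self.max_spurs,
        )


_BLOCK_KEYS = {
    "pulse": {
        "n_electrons": "n_electrons",
        "pulse_duration_s": "pulse_duration_s",
        "energy_ev": "energy_ev",
        "beam_fwhm_m": "beam_fwhm_m",
        "envelope": "envelope",
    },
    "track": {
        "spur_energy_min_ev": "spur_energy_min_ev",
        "spur_energy_max_ev": "spur_energy_max_ev",
        "cutoff_energy_ev": "cutoff_energy_ev",
        "sigma_heavy_m": "sigma_heavy_m",
        "sigma_electron_m": "sigma_electron_m",
        "pc_offset_s": "pc_offset_s",
        "max_spurs": "max_spurs",
        "initial_yields": "initial_yields",
    },
    "chemistry": {
        "species_table": "species_table",
        "reaction_table": "reaction_table",
        "debye": "debye",
        "o2_concentration_m": "o2_concentration_m",
        "t_end_rule": "t_end_rule",
        "window_s": "window_s",
        "cutoff_factor": "cutoff_factor",
        "r_cut_max_m": "r_cut_max_m",
    },
    "sweep": {
        "tau_grid_s": "tau_grid_s",
        "replicates": "replicates",
        "species": "sweep_species",
    },
    "run": {
        "seed": "seed",
        "output_dir": "output_dir",
        "log_level": "log_level",
    },
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML config; unknown keys are schema errors."""
    path = Path(path)
    try:
        raw_bytes = path.read_bytes()
        data = tomllib.loads(raw_bytes.decode())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"malformed TOML in {path}: {exc}") from None

    cfg = RunConfig()
    bad: list[str] = []
    for block, entries in data.items():
        if block not in _BLOCK_KEYS:
            bad.append(block)
            continue
        if not isinstance(entries, dict):
            bad.append(block)
            continue
        for key, value in entries.items():
            if key not in _BLOCK_KEYS[block]:
                bad.append(f"{block}.{key}")
                continue
            attr = _BLOCK_KEYS[block][key]
            if isinstance(value, list):
                value = tuple(value)
            setattr(cfg, attr, value)
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(bad))}")

    for name in ("species_table", "reaction_table"):
        p = getattr(cfg, name)
        if p and not Path(p).exists():
            raise ConfigError(f"chemistry.{name}: file not found: {p}")

    if not STUDIED_TAU[0] <= cfg.pulse_duration_s <= STUDIED_TAU[1]:
        warnings.warn(
            f"pulse_duration_s={cfg.pulse_duration_s:g} outside studied range "
            f"{STUDIED_TAU}"
        )
    if not STUDIED_ENERGY[0] <= cfg.energy_ev <= STUDIED_ENERGY[1]:
        warnings.warn(
            f"energy_ev={cfg.energy_ev:g} outside studied range {STUDIED_ENERGY}"
        )
    if not STUDIED_N_ELECTRONS[0] <= cfg.n_electrons <= STUDIED_N_ELECTRONS[1]:
        warnings.warn(
            f"n_electrons={cfg.n_electrons} outside studied range {STUDIED_N_ELECTRONS}"
        )

    cfg.config_hash = hashlib.sha256(raw_bytes).hexdigest()[:16]
    return cfg


def default_config_toml() -> str:
    """A fully-commented default config file (make-fixtures output)."""
    return """\
# pulsechem run configuration (all physics defaults shown explicitly)

[pulse]
n_electrons = 10
pulse_duration_s = 1e-12
energy_ev = 1e4
beam_fwhm_m = 5e-6          # 5 um FWHM Gaussian beam
envelope = "tophat"          # or "gaussian"

[track]
spur_energy_min_ev = 17.0    # spur energies sampled uniform on this interval
spur_energy_max_ev = 100.0
cutoff_energy_ev = 500.0     # transport stops below this residual energy
sigma_heavy_m = 2.0e-9       # spur spread, heavy species
sigma_electron_m = 5.0e-9    # e_aq thermalisation spread
pc_offset_s = 1e-12          # physicochemical stage duration

[track.initial_yields]       # per 100 eV at ~1 ps; H3O+ count pairs to e_aq
e_aq = 4.8
OH = 5.5
H = 0.62
H2 = 0.15
"H3O+" = 4.8

[chemistry]
# species_table / reaction_table default to the bundled pure-water set
debye = false                # Coulomb-corrected radii for charged pairs
o2_concentration_m = 0.0     # mol/dm3 dissolved O2 (pseudo-first-order)
t_end_rule = "pulse_end"     # or "pulse_plus_window"
window_s = 1e-6
cutoff_factor = 10.0         # pair cutoff: R + factor*sqrt(2 D' t)
r_cut_max_m = 3e-7

[sweep]
tau_grid_s = [1e-13, 1e-12, 1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6]
replicates = 8
species = ["OH", "e_aq", "H2O2", "H3O+"]

[run]
seed = 1
output_dir = "pulsechem_out"
log_level = "info"
"""
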