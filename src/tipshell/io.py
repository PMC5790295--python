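"""Configuration files, analytic test fixtures and result serialization.

Config files are flat structured text (TOML or JSON) with two mutually
exclusive parameter blocks, ``physical`` or ``dimensionless``, plus an
optional ``numerics`` block.  Unknown keys are an error: every number the
pipeline reports must be traceable to a config value or a computed field.

Result files are deterministic byte-for-byte for identical inputs: CSV with
comma separator, '.' decimal, 17-significant-digit scientific notation
(round-trip exact for doubles) and '#'-prefixed metadata header lines; JSON
with sorted keys.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .dynamics import (
    Outcome,
    SteadyStateProfile,
    TrajectoryRecord,
    WallState,
)
from .mechanics import ShellShape
from .params import DimensionlessParameters, NumericsConfig, PhysicalParameters

__all__ = [
    "RunConfig",
    "ConfigError",
    "FixtureShape",
    "load_config",
    "save_config",
    "make_fixture",
    "write_results",
]

_FMT = "%.17g"


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: one parameter block plus numerics."""

    physical: PhysicalParameters | None
    dimensionless: DimensionlessParameters | None
    numerics: NumericsConfig

    def __post_init__(self) -> None:
        if (self.physical is None) == (self.dimensionless is None):
            raise ConfigError(
                "exactly one of 'physical'/'dimensionless' must be given")

    @property
    def params(self) -> DimensionlessParameters:
        """The dimensionless groups actually driving the simulation."""
        from .params import nondimensionalize
        if self.dimensionless is not None:
            return self.dimensionless
        return nondimensionalize(self.physical)

    def to_dict(self) -> dict:
        out: dict = {"numerics": self.numerics.to_dict()}
        if self.physical is not None:
            out["physical"] = dataclasses.asdict(self.physical)
        else:
            out["dimensionless"] = self.dimensionless.to_dict()
        return out


def _build_block(cls, name: str, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{name}' block: {', '.join(sorted(unknown))}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a TOML or JSON run configuration."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(text.decode())
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError("top level must be a table/object")
    unknown = set(data) - {"physical", "dimensionless", "numerics"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    if ("physical" in data) == ("dimensionless" in data):
        raise ConfigError(
            "exactly one of 'physical'/'dimensionless' must be given")
    phys = (_build_block(PhysicalParameters, "physical", data["physical"])
            if "physical" in data else None)
    dim = (_build_block(DimensionlessParameters, "dimensionless",
                        data["dimensionless"])
           if "dimensionless" in data else None)
    nume = _build_block(NumericsConfig, "numerics", data.get("numerics", {}))
    return RunConfig(physical=phys, dimensionless=dim, numerics=nume)


def save_config(config: RunConfig, path) -> None:
    """Serialize a config to JSON; load_config round-trips it unchanged."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2,
                                     sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------

_FAMILIES = ("sphere", "cylinder", "capped_cylinder")


@dataclass(frozen=True)
class FixtureShape:
    """Analytic shape family used as a numerical oracle in tests.

    * ``sphere``: radius ``a`` cap, theta = s/a, r = a sin(s/a);
      kappa_s = kappa_phi = 1/a everywhere.
    * ``cylinder``: radius ``a`` tube (no apex), theta = pi/2, r = a;
      kappa_s = 0, kappa_phi = 1/a.
    * ``capped_cylinder``: hemisphere of radius ``a`` joined to a tube;
      theta continuous, kappa_s jumps from 1/a to 0 at s = a*pi/2 while
      kappa_phi = 1/a throughout.
    """

    family: str
    a: float  #: sphere/tube radius
    n_grid: int = 101
    domain_len: float | None = None  #: defaults to a*pi/2 (sphere) or 3a

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown fixture family {self.family!r}")
        if self.a <= 0:
            raise ValueError("fixture radius must be > 0")
        if self.n_grid < 7:
            raise ValueError("n_grid must be >= 7")


def make_fixture(f: FixtureShape, with_state: bool = False,
                 h: float = 1.0, rho_A: float = 0.5, rho_I: float = 0.5):
    """Sample the analytic fixture on a uniform arclength grid.

    The exact theta, r and closed-form curvatures are attached (sampled, not
    computed), so the shape can serve as an oracle for the discrete
    operators.  With ``with_state=True`` a uniform WallState is returned
    instead of the bare shape.
    """
    a = f.a
    if f.family == "sphere":
        L = f.domain_len if f.domain_len is not None else a * np.pi / 2
        s = np.linspace(0.0, L, f.n_grid)
        theta = s / a
        r = a * np.sin(theta)
        z = a * (np.cos(theta) - 1.0)
        ks = np.full(f.n_grid, 1.0 / a)
        kp = np.full(f.n_grid, 1.0 / a)
    elif f.family == "cylinder":
        L = f.domain_len if f.domain_len is not None else 3.0 * a
        s = np.linspace(0.0, L, f.n_grid)
        theta = np.full(f.n_grid, np.pi / 2)
        r = np.full(f.n_grid, a)
        z = -s
        ks = np.zeros(f.n_grid)
        kp = np.full(f.n_grid, 1.0 / a)
    else:  # capped_cylinder
        L = f.domain_len if f.domain_len is not None else 3.0 * a
        s = np.linspace(0.0, L, f.n_grid)
        s_cap = a * np.pi / 2
        theta = np.minimum(s / a, np.pi / 2)
        r = np.where(s < s_cap, a * np.sin(theta), a)
        z = np.where(s < s_cap, a * (np.cos(theta) - 1.0), -a - (s - s_cap))
        ks = np.where(s < s_cap, 1.0 / a, 0.0)
        kp = np.full(f.n_grid, 1.0 / a)
    shape = ShellShape(s=s, r=r, theta=theta, kappa_s=ks, kappa_phi=kp, z=z)
    if not with_state:
        return shape
    n = f.n_grid
    return WallState(shape=shape, h=np.full(n, h), rho_A=np.full(n, rho_A),
                     rho_I=np.full(n, rho_I), t=0.0)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ("s", "r", "theta", "kappa_s", "kappa_phi", "h", "u", "vn",
                   "sigma_ss", "sigma_pp", "eps_s", "eps_phi", "rho_A",
                   "rho_I")


def _meta_lines(record: TrajectoryRecord) -> list[str]:
    meta = {"tipshell_version": __version__,
            "outcome": record.outcome.value,
            "constitutive": record.constitutive}
    meta.update({f"param_{k}": v for k, v in record.params.to_dict().items()})
    meta.update({f"numerics_{k}": v
                 for k, v in record.numerics.to_dict().items()})
    return [f"# {k}={v}" for k, v in meta.items()]


def _write_csv(path: Path, meta: list[str], columns, arrays) -> None:
    lines = list(meta)
    lines.append(",".join(columns))
    data = np.column_stack(arrays)
    for row in data:
        lines.append(",".join(_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")


def write_results(record: TrajectoryRecord,
                  profile: SteadyStateProfile | None,
                  out_dir,
                  trajectory_csv: str = "trajectory.csv",
                  profile_csv: str = "profile.csv",
                  json_summary: str = "summary.json") -> dict:
    """Write trajectory CSV, profile CSV (stable runs only) and JSON summary.

    Returns the paths written.  Files are deterministic for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = _meta_lines(record)
    written = {}

    p = out_dir / trajectory_csv
    _write_csv(p, meta,
               ("t", "h0", "rhoA0", "rhoI0", "residual", "tip_speed"),
               (record.t, record.h0, record.rhoA0, record.rhoI0,
                record.residual, record.tip_speed))
    written["trajectory"] = p

    if profile is not None:
        f = profile.fields
        p = out_dir / profile_csv
        _write_csv(p, meta, PROFILE_COLUMNS,
                   tuple(np.asarray(f[c], float) for c in PROFILE_COLUMNS))
        written["profile"] = p

    summary = {
        "tipshell_version": __version__,
        "outcome": record.outcome.value,
        "error": record.error,
        "constitutive": record.constitutive,
        "params": record.params.to_dict(),
        "numerics": record.numerics.to_dict(),
        "t_end": float(record.t[-1]),
        "final_residual": float(record.residual[-1]),
        "mass_drift": float(record.mass_drift),
        "synthase_drift": float(record.synthase_drift),
        "observables": (profile.observables.to_dict()
                        if profile is not None else None),
        "steady_residual": (float(profile.residual)
                            if profile is not None else None),
    }
    p = out_dir / json_summary
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written["summary"] = p
    return written
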