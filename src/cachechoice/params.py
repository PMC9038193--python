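"""The 12-parameter vector of the site-choice model.

Order and units (raw vector, exactly as penalized by the Ridge term):

==  =============  =================================================
z   name           meaning / units
==  =============  =================================================
1   gamma_prv      log10 amplitude, proximity to previous site
2   sigma_prv      Gaussian width of the proximity effect, cm
3   gamma_occ      log10 amplitude, occupied sites
4   sigma_occ      Gaussian width, occupied sites, cm
5   gamma_emp      log10 amplitude, checked-empty sites
6   sigma_emp      Gaussian width, checked-empty sites, cm
7   gamma_occc     log10 amplitude, feeder-open-phase caches
8   gamma_occr     log10 amplitude, recaches (feeder-closed caches)
9   inv_tau_occ    inverse memory-decay timescale, 1/s
10  inv_tau_emp    inverse memory-decay timescale, 1/s
11  inv_nu_occ     inverse memory capacity, 1/site
12  inv_nu_emp     inverse memory capacity, 1/site
==  =============  =================================================

Timescales and capacities enter as inverses so that the Ridge penalty pulls
toward no decay (tau, nu -> infinity) rather than toward instant decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields

import numpy as np

PARAM_NAMES = (
    "gamma_prv",
    "sigma_prv",
    "gamma_occ",
    "sigma_occ",
    "gamma_emp",
    "sigma_emp",
    "gamma_occc",
    "gamma_occr",
    "inv_tau_occ",
    "inv_tau_emp",
    "inv_nu_occ",
    "inv_nu_emp",
)

#: below this width (cm) a Gaussian kernel is treated as a site-local indicator
SIGMA_LOCAL_CM = 1e-6


@dataclass(frozen=True)
class ParameterVector:
    """Named view of the raw 12-vector theta."""

    gamma_prv: float = 0.0
    sigma_prv: float = 0.0
    gamma_occ: float = 0.0
    sigma_occ: float = 0.0
    gamma_emp: float = 0.0
    sigma_emp: float = 0.0
    gamma_occc: float = 0.0
    gamma_occr: float = 0.0
    inv_tau_occ: float = 0.0
    inv_tau_emp: float = 0.0
    inv_nu_occ: float = 0.0
    inv_nu_emp: float = 0.0

    def __post_init__(self):
        for name in ("sigma_prv", "sigma_occ", "sigma_emp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("inv_tau_occ", "inv_tau_emp", "inv_nu_occ", "inv_nu_emp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, theta) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (12,):
            raise ValueError("theta must have length 12")
        return cls(**dict(zip(PARAM_NAMES, theta)))

    def replace(self, **kwargs) -> "ParameterVector":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return ParameterVector(**current)

    # timescales on the scale they are usually reported
    @property
    def tau_occ_min(self) -> float:
        """Memory-decay timescale for occupied sites, minutes."""
        return np.inf if self.inv_tau_occ == 0 else 1.0 / self.inv_tau_occ / 60.0

    @property
    def tau_emp_min(self) -> float:
        return np.inf if self.inv_tau_emp == 0 else 1.0 / self.inv_tau_emp / 60.0

    @property
    def nu_occ_sites(self) -> float:
        """Memory capacity for occupied sites, sites."""
        return np.inf if self.inv_nu_occ == 0 else 1.0 / self.inv_nu_occ

    @property
    def nu_emp_sites(self) -> float:
        return np.inf if self.inv_nu_emp == 0 else 1.0 / self.inv_nu_emp

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {n: getattr(self, n) for n in PARAM_NAMES},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ParameterVector":
        with open(path) as fh:
            return cls(**json.load(fh))
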