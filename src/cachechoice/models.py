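"""Registry of the twelve nested site-choice models.

Each model fixes some of the twelve parameters at zero and frees the rest:

====  =======================================================  ====
M     free parameters                                          f_M
====  =======================================================  ====
0     none (baseline: choices drawn from p_bias)                0
1     gamma_prv, sigma_prv                                      2
2     + gamma_occ                                               3
3     + gamma_emp                                               4
4     Model 3 + sigma_occ                                       5
5     Model 3 + sigma_emp                                       5
6     gamma_prv, sigma_prv, gamma_occc                          3
7     + gamma_occr                                              4
8-11  Model 3 + one of 1/tau_occ, 1/tau_emp, 1/nu_occ,          5
      1/nu_emp on [0, inf)
====  =======================================================  ====

Amplitudes gamma are free on the whole real line; widths sigma and the
inverse timescales/capacities are free on the non-negative half-line. For
optimization, unbounded ranges are realized as wide finite boxes (the
Ridge penalty keeps optima far from the box edges); box widths are
configurable through :class:`ModelSpec.bounds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import PARAM_NAMES

#: permitted-range codes per parameter: "zero", "half" ([0, inf)), "real"
_RANGES = {
    0: {},
    1: {"gamma_prv": "real", "sigma_prv": "half"},
    2: {"gamma_prv": "real", "sigma_prv": "half", "gamma_occ": "real"},
    3: {
        "gamma_prv": "real",
        "sigma_prv": "half",
        "gamma_occ": "real",
        "gamma_emp": "real",
    },
    6: {"gamma_prv": "real", "sigma_prv": "half", "gamma_occc": "real"},
    7: {
        "gamma_prv": "real",
        "sigma_prv": "half",
        "gamma_occc": "real",
        "gamma_occr": "real",
    },
}
_RANGES[4] = {**_RANGES[3], "sigma_occ": "half"}
_RANGES[5] = {**_RANGES[3], "sigma_emp": "half"}
_RANGES[8] = {**_RANGES[3], "inv_tau_occ": "half"}
_RANGES[9] = {**_RANGES[3], "inv_tau_emp": "half"}
_RANGES[10] = {**_RANGES[3], "inv_nu_occ": "half"}
_RANGES[11] = {**_RANGES[3], "inv_nu_emp": "half"}

#: default box half-widths per parameter class
GAMMA_BOX = 10.0        # |gamma| <= 10 on the log10 scale
SIGMA_BOX_CM = 100.0    # > arena diagonal of the reference apparatus
INV_TAU_BOX = 1.0       # 1/s
INV_NU_BOX = 1.0        # 1/site


def _default_bounds(name: str, kind: str) -> tuple[float, float]:
    if kind == "zero":
        return (0.0, 0.0)
    if name.startswith("gamma"):
        return (-GAMMA_BOX if kind == "real" else 0.0, GAMMA_BOX)
    if name.startswith("sigma"):
        return (0.0, SIGMA_BOX_CM)
    if name.startswith("inv_tau"):
        return (0.0, INV_TAU_BOX)
    return (0.0, INV_NU_BOX)


@dataclass(frozen=True)
class ModelSpec:
    """One row of the model family: permitted ranges and bookkeeping."""

    model_id: int
    ranges: dict[str, str]  # parameter name -> "real" | "half"
    bounds: tuple[tuple[float, float], ...] = field(default=None)

    def __post_init__(self):
        if self.bounds is None:
            b = tuple(
                _default_bounds(n, self.ranges.get(n, "zero"))
                for n in PARAM_NAMES
            )
            object.__setattr__(self, "bounds", b)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n in self.ranges)

    @property
    def free_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(PARAM_NAMES) if n in self.ranges])

    @property
    def n_free(self) -> int:
        """Number of free parameters f_M."""
        return len(self.ranges)

    def permitted(self, name: str) -> str:
        """Permitted-range code for a parameter: 'zero', 'half', or 'real'."""
        return self.ranges.get(name, "zero")


def get_model(model_id: int) -> ModelSpec:
    """Look up a model by index 0..11."""
    if model_id not in _RANGES:
        raise ValueError(f"unknown model id {model_id}; expected 0..11")
    return ModelSpec(model_id, dict(_RANGES[model_id]))


ALL_MODELS = tuple(sorted(_RANGES))

#: regularization weight per task (different data volumes)
DEFAULT_LAMBDA = {"caching": 1.0, "retrieval": 10.0}

#: likelihood mask conventionally paired with each task
DEFAULT_MASK = {"caching": "caches_caching", "retrieval": "checks_until_find"}
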