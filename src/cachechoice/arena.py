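"""Arena geometry: discrete interaction sites on a grid plus feeders.

The reference apparatus is a 61 x 61 cm square arena whose floor holds an
8 x 8 grid of concealed cache sites (7.1 cm between neighboring sites) and
four motorized feeders, one per quadrant, for a total of S = 68 sites.
All distances are Euclidean, in centimeters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: spacing between adjacent cache sites in the reference arena, cm
DEFAULT_SPACING_CM = 7.1

CACHE_SITE = "cache"
FEEDER = "feeder"


@dataclass(frozen=True)
class ArenaGeometry:
    """Site coordinates and kinds for a caching arena.

    Parameters
    ----------
    locations : (S, 2) array of site centers in cm.
    kinds : length-S sequence of ``"cache"`` or ``"feeder"``.
    grid_shape : (rows, cols) of the cache-site grid, metadata only.
    spacing_cm : pitch of the cache-site grid.
    """

    locations: np.ndarray
    kinds: tuple[str, ...]
    grid_shape: tuple[int, int] = (8, 8)
    spacing_cm: float = DEFAULT_SPACING_CM
    _distance: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        loc = np.asarray(self.locations, dtype=float)
        if loc.ndim != 2 or loc.shape[1] != 2:
            raise ValueError("locations must be an (S, 2) array")
        if not np.all(np.isfinite(loc)):
            raise ValueError("site locations must be finite")
        if len(self.kinds) != loc.shape[0]:
            raise ValueError("kinds length must match number of sites")
        bad = set(self.kinds) - {CACHE_SITE, FEEDER}
        if bad:
            raise ValueError(f"unknown site kinds: {bad}")
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "_distance", None)

    @property
    def n_sites(self) -> int:
        """Total number of sites S (cache sites plus feeders)."""
        return self.locations.shape[0]

    @property
    def cache_sites(self) -> np.ndarray:
        """Indices of cache sites."""
        return np.array([i for i, k in enumerate(self.kinds) if k == CACHE_SITE])

    @property
    def feeders(self) -> np.ndarray:
        """Indices of feeder sites."""
        return np.array([i for i, k in enumerate(self.kinds) if k == FEEDER])

    @property
    def is_cache_site(self) -> np.ndarray:
        """Boolean mask over sites, True at cache sites."""
        return np.array([k == CACHE_SITE for k in self.kinds])

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances d(s, s') between site centers, cm.

        Symmetric, non-negative, zero on the diagonal. Cached after the
        first call.
        """
        if self._distance is None:
            diff = self.locations[:, None, :] - self.locations[None, :, :]
            d = np.sqrt((diff**2).sum(axis=2))
            object.__setattr__(self, "_distance", d)
        return self._distance

    def to_json(self, path) -> None:
        payload = {
            "locations": self.locations.tolist(),
            "kinds": list(self.kinds),
            "grid_shape": list(self.grid_shape),
            "spacing_cm": self.spacing_cm,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ArenaGeometry":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            locations=np.asarray(payload["locations"], dtype=float),
            kinds=tuple(payload["kinds"]),
            grid_shape=tuple(payload["grid_shape"]),
            spacing_cm=float(payload["spacing_cm"]),
        )


def default_arena(spacing_cm: float = DEFAULT_SPACING_CM) -> ArenaGeometry:
    """The reference arena: 8 x 8 cache-site grid plus four feeders, S = 68.

    Origin is at the arena center; cache sites occupy a grid with the given
    pitch. Feeders sit at the centers of the four quadrants (the apparatus
    places one feeder per quadrant; exact feeder coordinates are a
    convention of this package).
    """
    rows = cols = 8
    offs = (np.arange(rows) - (rows - 1) / 2.0) * spacing_cm
    grid = np.array([(x, y) for y in offs for x in offs])
    # quadrant centers: halfway from origin to each corner of the grid
    q = (rows - 1) / 4.0 * spacing_cm
    feeders = np.array([(q, q), (-q, q), (-q, -q), (q, -q)])
    locations = np.vstack([grid, feeders])
    kinds = (CACHE_SITE,) * (rows * cols) + (FEEDER,) * 4
    return ArenaGeometry(locations, kinds, (rows, cols), spacing_cm)


def distance_matrix(arena: ArenaGeometry) -> np.ndarray:
    """Functional alias for :meth:`ArenaGeometry.distance_matrix`."""
    return arena.distance_matrix()
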