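"""Demographic models for one or two demes, and the named model catalog.

A :class:`DemographicModel` is an ordered list of epochs (oldest first) in
coalescent-scaled ("genetic") units: sizes are ratios ``nu = N / Ne_anc`` to
the ancestral effective size, times are in units of ``2 * Ne_anc``
generations, and migration is scaled as ``M = 2 * Ne_anc * m`` with ``m``
the per-generation migrant fraction of the destination deme.  Before the
first listed epoch the population sits at equilibrium with ``nu = 1``.  An
optional split event divides the single ancestral deme into two at the
start of one epoch.

The catalog enumerates the fixed set of candidate histories compared during
model selection: three single-population size-change models (``sc1ns``,
``sc2ns``, ``sc3ns``, in which the two samples are subsamples of one deme),
four isolation-with-migration variants (``s2m``, ``s2msm``, ``sc2el``,
``sc2elsm``), and ``gadma_best``, the structure found by a genetic-algorithm
search: ancestral sudden growth, a recent split with linear growth in deme 1
and sudden growth in deme 2, and one-way gene flow from deme 1 to deme 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "Epoch",
    "DemographicModel",
    "CatalogEntry",
    "CATALOG",
    "default_bounds",
    "model_to_dict",
    "model_from_dict",
    "load_model_yaml",
    "dump_model_yaml",
]

DYNAMICS = ("sudden", "linear", "exponential")


@dataclass
class Epoch:
    """One time interval of a demographic history (genetic units).

    ``sizes`` are the per-deme size ratios reached at the *end* of the
    epoch; ``dynamics`` states how each deme interpolates from its size at
    the epoch start ("sudden" holds the end size throughout).  ``migration``
    is a ``(d, e)`` matrix of scaled rates ``M`` for genes moving forward in
    time from deme ``d`` to deme ``e``.
    """

    duration: float
    sizes: tuple[float, ...]
    dynamics: tuple[str, ...] | None = None
    migration: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        self.sizes = tuple(float(s) for s in self.sizes)
        if any(s <= 0 for s in self.sizes):
            raise ValueError("deme sizes must be > 0")
        k = len(self.sizes)
        if self.dynamics is None:
            self.dynamics = ("sudden",) * k
        self.dynamics = tuple(self.dynamics)
        if len(self.dynamics) != k or any(d not in DYNAMICS for d in self.dynamics):
            raise ValueError(f"dynamics must be one of {DYNAMICS} per deme")
        if self.migration is None:
            self.migration = np.zeros((k, k))
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (k, k) or np.any(self.migration < 0):
            raise ValueError("migration must be a non-negative (k, k) matrix")

    @property
    def n_demes(self) -> int:
        return len(self.sizes)


@dataclass
class DemographicModel:
    """Ordered epochs (oldest to newest) with an optional split event.

    ``split_epoch`` is the index of the epoch at whose start the single
    ancestral deme divides into two; epochs before it must have one deme and
    epochs from it on must have two.
    """

    epochs: list[Epoch] = field(default_factory=list)
    split_epoch: int | None = None

    def __post_init__(self) -> None:
        for k, ep in enumerate(self.epochs):
            expected = 1 if self.split_epoch is None or k < self.split_epoch else 2
            if ep.n_demes != expected:
                raise ValueError(
                    f"epoch {k} has {ep.n_demes} demes, expected {expected} "
                    f"(split at {self.split_epoch})"
                )
        if self.split_epoch is not None and not 0 <= self.split_epoch < max(len(self.epochs), 1):
            raise ValueError("split_epoch out of range")

    @property
    def has_split(self) -> bool:
        return self.split_epoch is not None

    def size_at_epoch_start(self, k: int) -> tuple[float, ...]:
        """Per-deme size ratio at the start of epoch ``k`` (forward time)."""
        if k == 0:
            prev = (1.0,)
        else:
            prev = self.epochs[k - 1].sizes
        if self.split_epoch is not None and k == self.split_epoch:
            # daughters inherit the ancestral size at the split
            return (prev[0], prev[0])
        return prev


# -- catalog ---------------------------------------------------------------


@dataclass
class CatalogEntry:
    name: str
    description: str
    param_names: tuple[str, ...]
    build: Callable[[Sequence[float]], DemographicModel]

    @property
    def k_free(self) -> int:
        """Free parameters counted for AIC: model parameters plus theta."""
        return len(self.param_names) + 1

    def bounds(self) -> list[tuple[float, float]]:
        return [_PARAM_BOUNDS[p[0]] for p in self.param_names]


# bounds by parameter family (first letter: nu / T / M)
_PARAM_BOUNDS = {
    "n": (1e-3, 1e3),  # nu*
    "T": (1e-4, 5.0),
    "M": (0.0, 50.0),
}


def _mig(m12: float = 0.0, m21: float = 0.0) -> np.ndarray:
    """Forward-flow migration matrix from dadi-style rates.

    ``m12`` is gene flow into deme 1 from deme 2 (forward direction
    2 -> 1); ``m21`` into deme 2 from deme 1.  Row = source, column =
    destination.
    """
    return np.array([[0.0, m21], [m12, 0.0]])


def _sc1ns(p: Sequence[float]) -> DemographicModel:
    return DemographicModel(epochs=[])


def _sc2ns(p: Sequence[float]) -> DemographicModel:
    nu, T = p
    return DemographicModel(epochs=[Epoch(T, (nu,))])


def _sc3ns(p: Sequence[float]) -> DemographicModel:
    nu1, T1, nu2, T2 = p
    return DemographicModel(epochs=[Epoch(T1, (nu1,)), Epoch(T2, (nu2,))])


def _s2m(p: Sequence[float]) -> DemographicModel:
    nu1, nu2, T, M12, M21 = p
    return DemographicModel(
        epochs=[Epoch(T, (nu1, nu2), migration=_mig(M12, M21))], split_epoch=0
    )


def _s2msm(p: Sequence[float]) -> DemographicModel:
    nu1, nu2, T, M = p
    return DemographicModel(
        epochs=[Epoch(T, (nu1, nu2), migration=_mig(M, M))], split_epoch=0
    )


def _sc2el(p: Sequence[float]) -> DemographicModel:
    nuA, TA, nu1, nu2, T, M12, M21 = p
    return DemographicModel(
        epochs=[Epoch(TA, (nuA,)), Epoch(T, (nu1, nu2), migration=_mig(M12, M21))],
        split_epoch=1,
    )


def _sc2elsm(p: Sequence[float]) -> DemographicModel:
    nuA, TA, nu1, nu2, T, M = p
    return DemographicModel(
        epochs=[Epoch(TA, (nuA,)), Epoch(T, (nu1, nu2), migration=_mig(M, M))],
        split_epoch=1,
    )


def _gadma_best(p: Sequence[float]) -> DemographicModel:
    nuA, TA, nu1, nu2, T, M21 = p
    return DemographicModel(
        epochs=[
            Epoch(TA, (nuA,)),
            Epoch(
                T,
                (nu1, nu2),
                dynamics=("linear", "sudden"),
                migration=_mig(0.0, M21),
            ),
        ],
        split_epoch=1,
    )


CATALOG: dict[str, CatalogEntry] = {
    e.name: e
    for e in [
        CatalogEntry("sc1ns", "No split, one epoch", (), _sc1ns),
        CatalogEntry("sc2ns", "No split, two epochs", ("nu", "T"), _sc2ns),
        CatalogEntry("sc3ns", "No split, three epochs", ("nu1", "T1", "nu2", "T2"), _sc3ns),
        CatalogEntry(
            "s2m",
            "One split, one epoch with asymmetric migration",
            ("nu1", "nu2", "T", "M12", "M21"),
            _s2m,
        ),
        CatalogEntry(
            "s2msm",
            "One split, one epoch with symmetric migration",
            ("nu1", "nu2", "T", "M"),
            _s2msm,
        ),
        CatalogEntry(
            "sc2el",
            "One split, two epochs with asymmetric migration",
            ("nuA", "TA", "nu1", "nu2", "T", "M12", "M21"),
            _sc2el,
        ),
        CatalogEntry(
            "sc2elsm",
            "One split, two epochs with symmetric migration",
            ("nuA", "TA", "nu1", "nu2", "T", "M"),
            _sc2elsm,
        ),
        CatalogEntry(
            "gadma_best",
            "Ancestral sudden growth, split with linear growth in deme 1 and "
            "one-way gene flow deme 1 -> deme 2",
            ("nuA", "TA", "nu1", "nu2", "T", "M21"),
            _gadma_best,
        ),
    ]
}


def default_bounds(name: str) -> list[tuple[float, float]]:
    """Search box per free parameter of a catalog model (theta excluded;
    it is profiled analytically)."""
    if name not in CATALOG:
        raise KeyError(f"unknown model {name!r}; catalog has {sorted(CATALOG)}")
    return CATALOG[name].bounds()


# -- YAML round trip for explicit (non-catalog) models ---------------------


def model_to_dict(model: DemographicModel) -> dict:
    return {
        "split_epoch": model.split_epoch,
        "epochs": [
            {
                "duration": ep.duration,
                "sizes": list(ep.sizes),
                "dynamics": list(ep.dynamics),
                "migration": ep.migration.tolist(),
            }
            for ep in model.epochs
        ],
    }


def model_from_dict(d: dict) -> DemographicModel:
    epochs = [
        Epoch(
            duration=e["duration"],
            sizes=tuple(e["sizes"]),
            dynamics=tuple(e.get("dynamics") or ("sudden",) * len(e["sizes"])),
            migration=np.asarray(e["migration"]) if e.get("migration") is not None else None,
        )
        for e in d.get("epochs", [])
    ]
    return DemographicModel(epochs=epochs, split_epoch=d.get("split_epoch"))


def load_model_yaml(path) -> DemographicModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def dump_model_yaml(model: DemographicModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
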