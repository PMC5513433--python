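"""Free parameters of the model, their bounds, and flat-vector views.

Per TF *a*: a scale factor ``A_a`` converting fluorescence x affinity into
statistical weight, a score-softening scale ``lambda_a``, and efficiencies —
``E_A`` (adaptor recruitment by an activating site), ``E_Q`` (quenching by a
repressing site), ``E_C`` (repressor-to-activator switching by coactivation).
The cooperative TF additionally carries ``omega``, the weight boost for a
nearest pair of its bound sites within ``d_omega`` bp edge-to-edge.

Globals: ``theta`` (energy barrier), ``beta`` (promoter-interaction gain per
adaptor), ``Rmax`` (saturating rate, carries the data scale) and ``alpha``
(window size in bp; structural, never fitted).

Bounds (fitting search space): A_a in [1e-6, 4], lambda in [0.5, 5],
omega in [1, 1000], E_Q and E_C in [0, 1], E_A in [0, 25], theta in [5, 25].
beta and Rmax bounds default to [1e-6, 1e2] and [1e-2, 1e4] (configurable).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

BOUNDS = {
    "A": (1e-6, 4.0),
    "lambda": (0.5, 5.0),
    "omega": (1.0, 1000.0),
    "E_A": (0.0, 25.0),
    "E_Q": (0.0, 1.0),
    "E_C": (0.0, 1.0),
    "theta": (5.0, 25.0),
    "beta": (1e-6, 1e2),
    "Rmax": (1e-2, 1e4),
}

# parameters spanning several orders of magnitude get log-scale proposal moves
LOG_SCALE = {"A", "omega", "beta", "Rmax"}


@dataclass(frozen=True)
class TFParameters:
    tf_name: str
    role: str  # "activator" | "repressor"
    A: float = 1.0
    lam: float = 1.0
    E_A: float = 0.0
    E_Q: float = 0.0
    E_C: float = 0.0
    coactivated_by: tuple[str, ...] = ()
    cooperative: bool = False
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("activator", "repressor"):
            raise ValueError(f"{self.tf_name}: role must be activator or repressor")
        _check("A", self.A, self.tf_name)
        _check("lambda", self.lam, self.tf_name)
        _check("omega", self.omega, self.tf_name)
        _check("E_A", self.E_A, self.tf_name)
        _check("E_Q", self.E_Q, self.tf_name)
        _check("E_C", self.E_C, self.tf_name)
        if self.role == "activator" and self.coactivated_by:
            raise ValueError(f"{self.tf_name}: only repressors can be coactivated")

    @property
    def is_coactivated(self) -> bool:
        return self.role == "repressor" and bool(self.coactivated_by)


@dataclass(frozen=True)
class GlobalParameters:
    theta: float = 12.0
    beta: float = 0.01
    Rmax: float = 255.0
    alpha: int = 1000

    def __post_init__(self) -> None:
        _check("theta", self.theta, "global")
        _check("beta", self.beta, "global")
        _check("Rmax", self.Rmax, "global")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


def _check(kind: str, value: float, owner: str) -> None:
    lo, hi = BOUNDS[kind]
    if not (lo <= value <= hi):
        raise ValueError(f"{owner}: {kind}={value} outside [{lo}, {hi}]")


_TF_FIELDS = {"A": "A", "lambda": "lam", "E_A": "E_A", "E_Q": "E_Q",
              "E_C": "E_C", "omega": "omega"}
_GLOBAL_FIELDS = ("theta", "beta", "Rmax")


@dataclass(frozen=True)
class ParameterSet:
    """All free parameters plus structural settings, with a flat-vector view.

    ``free`` lists the names (e.g. ``"A1.A"``, ``"theta"``) exposed to the
    optimizer; everything else is held fixed.  The flat <-> structured round
    trip is exact.
    """

    tfs: dict[str, TFParameters]
    globals_: GlobalParameters = field(default_factory=GlobalParameters)
    free: tuple[str, ...] = ()
    provenance: str = "loaded"  # fitted | loaded | sampled

    def __post_init__(self) -> None:
        for name in self.free:
            self._locate(name)  # validates
        coop = [t for t in self.tfs.values() if t.cooperative]
        if len(coop) > 1:
            raise ValueError("at most one cooperative TF is supported")
        for tf in self.tfs.values():
            for co in tf.coactivated_by:
                if co not in self.tfs:
                    raise ValueError(f"{tf.tf_name}: unknown coactivator {co!r}")
                if co == tf.tf_name:
                    raise ValueError(f"{tf.tf_name}: cannot coactivate itself")

    # -- flat-vector view ---------------------------------------------------

    def _locate(self, name: str):
        if name in _GLOBAL_FIELDS:
            return ("global", name)
        tf, _, kind = name.partition(".")
        if tf in self.tfs and kind in _TF_FIELDS:
            return ("tf", tf, kind)
        raise KeyError(f"unknown parameter {name!r}")

    def get(self, name: str) -> float:
        loc = self._locate(name)
        if loc[0] == "global":
            return getattr(self.globals_, loc[1])
        return getattr(self.tfs[loc[1]], _TF_FIELDS[loc[2]])

    def bounds_of(self, name: str) -> tuple[float, float]:
        loc = self._locate(name)
        kind = loc[1] if loc[0] == "global" else loc[2]
        return BOUNDS[kind]

    def log_scale_of(self, name: str) -> bool:
        loc = self._locate(name)
        kind = loc[1] if loc[0] == "global" else loc[2]
        return kind in LOG_SCALE

    def to_vector(self) -> np.ndarray:
        return np.array([self.get(n) for n in self.free], dtype=float)

    def with_vector(self, vector: Iterable[float], provenance: str | None = None) -> "ParameterSet":
        vector = list(vector)
        if len(vector) != len(self.free):
            raise ValueError("vector length does not match free parameter count")
        tfs = dict(self.tfs)
        glb = self.globals_
        for name, value in zip(self.free, vector):
            value = float(value)
            loc = self._locate(name)
            if loc[0] == "global":
                glb = replace(glb, **{loc[1]: value})
            else:
                _, tf, kind = loc
                tfs[tf] = replace(tfs[tf], **{_TF_FIELDS[kind]: value})
        return ParameterSet(tfs, glb, self.free, provenance or self.provenance)

    def with_free(self, free: Iterable[str]) -> "ParameterSet":
        return ParameterSet(self.tfs, self.globals_, tuple(free), self.provenance)

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "provenance": self.provenance,
            "free": list(self.free),
            "globals": {"theta": self.globals_.theta, "beta": self.globals_.beta,
                        "Rmax": self.globals_.Rmax, "alpha": self.globals_.alpha},
            "tfs": {
                name: {
                    "role": tf.role, "A": tf.A, "lambda": tf.lam,
                    "E_A": tf.E_A, "E_Q": tf.E_Q, "E_C": tf.E_C,
                    "coactivated_by": list(tf.coactivated_by),
                    "cooperative": tf.cooperative, "omega": tf.omega,
                }
                for name, tf in self.tfs.items()
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        doc = json.loads(text)
        tfs = {
            name: TFParameters(
                tf_name=name, role=d["role"], A=d["A"], lam=d["lambda"],
                E_A=d.get("E_A", 0.0), E_Q=d.get("E_Q", 0.0), E_C=d.get("E_C", 0.0),
                coactivated_by=tuple(d.get("coactivated_by", ())),
                cooperative=d.get("cooperative", False), omega=d.get("omega", 1.0),
            )
            for name, d in doc["tfs"].items()
        }
        g = doc["globals"]
        glb = GlobalParameters(g["theta"], g["beta"], g["Rmax"], g.get("alpha", 1000))
        return cls(tfs, glb, tuple(doc.get("free", ())), doc.get("provenance", "loaded"))

    def sample_free(self, rng: np.random.Generator) -> "ParameterSet":
        """Draw the free parameters uniformly within bounds (log-uniform for
        multi-decade parameters), as the random starting point of a fit."""
        values = []
        for name in self.free:
            lo, hi = self.bounds_of(name)
            if self.log_scale_of(name):
                values.append(math.exp(rng.uniform(math.log(lo), math.log(hi))))
            else:
                values.append(rng.uniform(lo, hi))
        return self.with_vector(values, provenance="sampled")
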