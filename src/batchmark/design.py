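"""Study design and model-structure specifications.

A batch-mark study follows the robust design: ``K`` primary periods, the
population closed within a period and open between periods, with period ``k``
containing ``T_k`` secondary capture occasions.  Consecutive primary periods
are separated by a known gap (in months), used by the monthly-survival model
structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class StudyDesign:
    """Robust-design layout of a batch-mark study.

    Parameters
    ----------
    K : int
        Number of primary periods (>= 1).
    Tks : tuple of int
        Secondary-occasion count per primary period, length ``K``.
    deltas : tuple of float
        Gaps between consecutive primary periods in months, length ``K - 1``.
        Defaults to unit spacing.
    """

    K: int
    Tks: tuple
    deltas: tuple = field(default=None)

    def __post_init__(self):
        Tks = tuple(int(t) for t in self.Tks)
        object.__setattr__(self, "Tks", Tks)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(Tks) != self.K:
            raise ValueError("Tks must have length K")
        if any(t < 1 for t in Tks):
            raise ValueError("every T_k must be >= 1")
        deltas = self.deltas
        if deltas is None:
            deltas = (1.0,) * (self.K - 1)
        deltas = tuple(float(d) for d in deltas)
        if len(deltas) != self.K - 1:
            raise ValueError("deltas must have length K - 1")
        if any(d <= 0 for d in deltas):
            raise ValueError("deltas must be positive")
        object.__setattr__(self, "deltas", deltas)

    @property
    def T(self) -> int:
        """Total number of secondary occasions."""
        return sum(self.Tks)

    @property
    def occasions(self):
        """All (period, occasion) pairs, 1-based, period-major order."""
        return [(k, t) for k in range(1, self.K + 1)
                for t in range(1, self.Tks[k - 1] + 1)]

    def occasion_offset(self, k: int) -> int:
        """0-based offset of the first occasion of period ``k`` (1-based)."""
        return sum(self.Tks[: k - 1])

    def to_dict(self):
        return {"K": self.K, "Tks": list(self.Tks), "deltas": list(self.deltas)}

    @classmethod
    def from_dict(cls, d):
        return cls(K=int(d["K"]), Tks=tuple(d["Tks"]),
                   deltas=tuple(d["deltas"]) if d.get("deltas") else None)


#: valid capture structures: per-occasion, per-period, constant
CAPTURE_STRUCTURES = ("t", "k", ".")
#: valid survival structures: per-interval, monthly, constant
SURVIVAL_STRUCTURES = ("k", "m", ".")

_MODEL_RE = re.compile(
    r"^\s*p\(\s*([tk.·])\s*\)\s*phi\(\s*([km.·])\s*\)\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the capture and survival probabilities.

    ``capture`` is one of ``"t"`` (per secondary occasion), ``"k"`` (per
    primary period) or ``"."`` (constant).  ``survival`` is one of ``"k"``
    (per inter-period interval), ``"m"`` (constant monthly survival ``S``
    with ``phi_k = S ** delta_k``) or ``"."`` (constant; implemented as
    ``"m"`` with unit spacing).  Entry probabilities are always fully
    time-dependent.
    """

    capture: str = "t"
    survival: str = "k"

    def __post_init__(self):
        cap = self.capture.replace("·", ".").lower()
        surv = self.survival.replace("·", ".").lower()
        if cap not in CAPTURE_STRUCTURES:
            raise ValueError(f"capture structure must be one of {CAPTURE_STRUCTURES}")
        if surv not in SURVIVAL_STRUCTURES:
            raise ValueError(f"survival structure must be one of {SURVIVAL_STRUCTURES}")
        object.__setattr__(self, "capture", cap)
        object.__setattr__(self, "survival", surv)

    @classmethod
    def parse(cls, s) -> "ModelSpec":
        """Parse a model string such as ``"p(t)phi(k)"`` (case-insensitive)."""
        if isinstance(s, ModelSpec):
            return s
        m = _MODEL_RE.match(s)
        if m is None:
            raise ValueError(
                f"unrecognized model string {s!r}; expected e.g. 'p(t)phi(k)' with "
                f"capture in {CAPTURE_STRUCTURES} and survival in {SURVIVAL_STRUCTURES}"
            )
        return cls(capture=m.group(1), survival=m.group(2))

    def n_capture_params(self, design: StudyDesign) -> int:
        return {"t": design.T, "k": design.K, ".": 1}[self.capture]

    def n_survival_params(self, design: StudyDesign) -> int:
        if design.K == 1:
            return 0
        return {"k": design.K - 1, "m": 1, ".": 1}[self.survival]

    def n_free_params(self, design: StudyDesign) -> int:
        """Free parameters: log N, capture, survival and K-1 entry logits."""
        return (1 + self.n_capture_params(design)
                + self.n_survival_params(design) + (design.K - 1))

    def __str__(self):
        return f"p({self.capture})phi({self.survival})"
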