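"""Dempster-rule fusion of evidence from two independent models.

For a singleton proposition A = (object -> label) with masses t and s
from two models, the non-normalised product table has mass
``kappa = (1-s)t + (1-t)s`` on the empty intersection; Dempster's rule
renormalises the agreeing cells,

    m(A) = t*s / (1 - kappa),

and the weight of conflict ``W = -log(1 - kappa)`` quantifies how much
the two sources disagree.  W is zero only under perfect agreement at
certainty (t = s in {0, 1}) and infinite at total contradiction
((t, s) = (0, 1) or (1, 0)), where combination is meaningless; that
case is flagged rather than raised so batch fusion completes and the
sanity check surfaces in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["JointMass", "dempster_combine", "combine_labelled_tables"]

_LOG_BASE = {"e": math.e, "2": 2.0, 2: 2.0}


@dataclass(frozen=True)
class JointMass:
    """Combined mass with its conflict diagnostics."""

    m: float
    conflict_weight: float
    contradictory: bool = False


def dempster_combine(t: float, s: float, log_base: str = "e") -> JointMass:
    """Combine two masses for the same singleton proposition.

    Symmetric in (t, s); a maximally uncertain source (mass 0.5) is
    neutral.  ``log_base`` selects the conflict-weight logarithm
    (natural log by default, base 2 available).
    """
    for name, v in (("t", t), ("s", s)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"mass {name} must be in [0, 1], got {v}")
    base = _LOG_BASE.get(log_base)
    if base is None:
        raise ValueError("log_base must be 'e' or '2'")
    if (t, s) in ((0.0, 1.0), (1.0, 0.0)):
        return JointMass(m=math.nan, conflict_weight=math.inf, contradictory=True)
    kappa = (1.0 - s) * t + (1.0 - t) * s
    agree = t * s + (1.0 - t) * (1.0 - s)  # stable form of 1 - kappa
    denom = 1.0 - kappa if 1.0 - kappa > 0 else agree
    # rounding in 1 - kappa can push the ratio epsilon past 1
    m = min(max(t * s / denom, 0.0), 1.0)
    w = -math.log(denom) / math.log(base)
    return JointMass(m=m, conflict_weight=w, contradictory=False)


def combine_labelled_tables(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    on: tuple[str, str] = ("image_id", "object_id"),
    mass_col: str = "p",
    log_base: str = "e",
) -> pd.DataFrame:
    """Fuse two labelled-object tables over the same detection run.

    Inner-joins on the object key and combines each table's belief
    (which equals its mass for singleton focal elements) per object.
    Any unmatched key on either side is an error listing the offenders:
    both tables must score the identical object set.
    """
    keys = list(on)
    k1 = set(map(tuple, table1[keys].itertuples(index=False)))
    k2 = set(map(tuple, table2[keys].itertuples(index=False)))
    if k1 != k2:
        unmatched = sorted(k1.symmetric_difference(k2))
        raise ValueError(f"tables label different objects; unmatched keys: {unmatched[:20]}")
    merged = table1[keys + [mass_col]].merge(
        table2[keys + [mass_col]], on=keys, suffixes=("_a", "_b")
    )
    t = merged[f"{mass_col}_a"].to_numpy(dtype=float)
    s = merged[f"{mass_col}_b"].to_numpy(dtype=float)
    joint = [dempster_combine(float(ti), float(si), log_base=log_base) for ti, si in zip(t, s)]
    out = merged.rename(columns={f"{mass_col}_a": "mass_a", f"{mass_col}_b": "mass_b"})
    out["joint_mass"] = [j.m for j in joint]
    out["conflict_weight"] = [j.conflict_weight for j in joint]
    out["contradictory"] = [j.contradictory for j in joint]
    return out


def nudge_extremes(masses: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Optionally pull exact 0/1 masses in by machine epsilon.

    Exact certainty is vanishingly unlikely in practice and breaks
    combination at total contradiction; this opt-in helper keeps batch
    fusion finite without materially changing the evidence.
    """
    eps = np.finfo(float).eps if eps is None else eps
    return np.clip(np.asarray(masses, dtype=float), eps, 1.0 - eps)
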