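"""Reaction-energetics arithmetic and error aggregation.

Pure energies-in, numbers-out: reaction energy (P-R), barrier height (TS-R),
transition-state-to-product gap (TS-P), bond dissociation energies, and
grouped mean-absolute-error reports.  Works on any model's outputs — no
geometry handling, by design.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReactionTriple:
    """Reactant / transition-state / product energies in a common unit."""

    reactant_energy: float
    ts_energy: float
    product_energy: float

    def __post_init__(self) -> None:
        for v in (self.reactant_energy, self.ts_energy, self.product_energy):
            if not np.isfinite(v):
                raise ValueError("reaction energies must be finite")


@dataclass(frozen=True)
class BDEInstance:
    """A bond-dissociation event: intact reactant plus product fragments."""

    reactant_energy: float
    product_fragment_energies: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.product_fragment_energies) < 1:
            raise ValueError("at least one product fragment is required")


def reaction_energetics(t: ReactionTriple) -> Tuple[float, float, float]:
    """(P-R, TS-R, TS-P): reaction energy, barrier height, TS-product gap.

    The thermodynamic-cycle identity TS-R = P-R + TS-P holds exactly.
    """
    p_minus_r = t.product_energy - t.reactant_energy
    ts_minus_r = t.ts_energy - t.reactant_energy
    ts_minus_p = t.ts_energy - t.product_energy
    return p_minus_r, ts_minus_r, ts_minus_p


def bde(instance: BDEInstance) -> float:
    """Bond dissociation energy: sum of fragment energies minus reactant."""
    return float(sum(instance.product_fragment_energies) - instance.reactant_energy)


def mae_report(
    pred: Sequence[float],
    ref: Sequence[float],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group and overall mean absolute error table.

    Returns a DataFrame with columns ``group``, ``n``, ``mae``; the final
    row (group ``"overall"``) aggregates everything.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {ref.shape} references")
    if groups is None:
        groups = ["all"] * len(pred)
    if len(groups) != len(pred):
        raise ValueError("group labels do not align with the energy vectors")
    err = np.abs(pred - ref)
    df = pd.DataFrame({"group": list(groups), "abs_error": err})
    per_group = (
        df.groupby("group", sort=True)["abs_error"]
        .agg(n="size", mae="mean")
        .reset_index()
    )
    overall = pd.DataFrame({"group": ["overall"], "n": [len(err)], "mae": [err.mean() if len(err) else np.nan]})
    return pd.concat([per_group, overall], ignore_index=True)
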