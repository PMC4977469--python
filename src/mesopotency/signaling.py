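"""Differential signaling-cascade propensity scoring.

Each component of an ordered signaling chain acts on its downstream
substrate either as an activator (+1) or an inhibitor (-1). The component's
signal-transduction propensity between two conditions is

    propensity = edge sign x log2FC(component)

so a down-regulated inhibitor (log2FC = -2 on a '-|' edge) contributes +2:
less inhibitor, more downstream signal. A run of large positive propensities
along consecutive components indicates consistently strengthened signaling;
the cascade is summarized by the arithmetic mean of its component
propensities.

The final gene component of a cascade, which feeds a non-gene terminal label
such as "Mesoderm Induction", is scored with sign +1 (the terminal label
itself is never scored); set ``include_terminal=False`` to score only
components with an explicit downstream gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io_formats import CascadeSpec


def component_propensity(log2fc: float, outgoing_edge_sign: int) -> float:
    """Signed propensity of one component: ``sign * log2fc``."""
    if outgoing_edge_sign not in (+1, -1):
        raise ValueError(f"edge sign must be +1 or -1, got {outgoing_edge_sign!r}")
    return outgoing_edge_sign * log2fc


@dataclass
class CascadeScore:
    """Per-component propensities and their mean for one cascade."""

    cascade: CascadeSpec
    components: list[str]
    propensities: list[float]

    @property
    def mean_propensity(self) -> float:
        return sum(self.propensities) / len(self.propensities)

    @property
    def consistent(self) -> bool:
        """All component propensities strictly positive."""
        return all(p > 0 for p in self.propensities)


def cascade_propensity(
    cascade: CascadeSpec, fc_map: dict[str, float], include_terminal: bool = True
) -> CascadeScore:
    """Score every component of a cascade with its own log2FC and the sign of
    its outgoing edge; the terminal gene component gets sign +1 when
    ``include_terminal`` is set."""
    scored = list(cascade.components) if include_terminal else cascade.components[:-1]
    missing = [c for c in scored if c not in fc_map]
    if missing:
        raise KeyError(f"cascade {cascade.name!r}: no log2FC for component(s) {missing}")
    propensities = []
    for i, comp in enumerate(scored):
        sign = cascade.edge_signs[i] if i < len(cascade.edge_signs) else +1
        propensities.append(component_propensity(fc_map[comp], sign))
    return CascadeScore(cascade, scored, propensities)


def round2(value: float) -> float:
    """Round to 2 decimals, halves away from zero (report convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def rank_cascades(scores: list[CascadeScore]) -> pd.DataFrame:
    """Cascades ordered by mean propensity (descending; ties by name).

    Columns: cascade, mean_propensity, consistent, n_components.
    """
    if not scores:
        raise ValueError("need at least one cascade score")
    rows = [
        {
            "cascade": s.cascade.name,
            "mean_propensity": s.mean_propensity,
            "consistent": s.consistent,
            "n_components": len(s.components),
        }
        for s in scores
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["mean_propensity", "cascade"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def score_table(scores: list[CascadeScore]) -> pd.DataFrame:
    """Long-form per-component report (cascade, component, sign, log2fc,
    propensity, cascade mean, consistency flag)."""
    rows = []
    for s in scores:
        for i, (comp, prop) in enumerate(zip(s.components, s.propensities)):
            sign = s.cascade.edge_signs[i] if i < len(s.cascade.edge_signs) else +1
            rows.append(
                {
                    "cascade": s.cascade.name,
                    "component": comp,
                    "sign": sign,
                    "log2fc": prop * sign,
                    "propensity": prop,
                    "mean_propensity": s.mean_propensity,
                    "consistent": s.consistent,
                }
            )
    return pd.DataFrame(rows)
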