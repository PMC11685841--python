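"""Background-dependent mutation effects and epistasis classification.

A mutation's effect is the label difference between a background variant and
the background plus the mutation, measured on whatever pairs of variants the
dataset actually contains.  Deviation from additivity for a mutation set S in
background B is

    epsilon = y(B u S) - [ y(B) + sum_m ( y(B u {m}) - y(B) ) ]

which is zero on a perfectly additive landscape.  A mutation is called
sign-epistatic when its measured effect exceeds +delta in some background and
falls below -delta in another; a pair is synergistic when its epsilon in the
wild-type background exceeds +delta.  delta (default 0.3 degC) absorbs
replicate-scale measurement noise.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .predictor import VariantRecord
from .variants import Mutation, Variant, WILD_TYPE


class MissingDataError(KeyError):
    """A variant required by an epistasis computation has no label."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"missing Tm labels for: {', '.join(self.missing)}")


@dataclass(frozen=True)
class EffectObservation:
    """Effect of adding ``target`` mutations on top of ``background`` (degC)."""

    target: tuple[Mutation, ...]
    background: Variant
    effect: float

    @property
    def combined(self) -> Variant:
        return self.background.union(self.target)


@dataclass
class EpistasisReport:
    """Sign/synergy calls with the observations that support them."""

    delta: float
    effects: dict[str, list[EffectObservation]] = field(default_factory=dict)
    sign_epistatic: dict[str, dict] = field(default_factory=dict)
    synergistic_pairs: dict[str, dict] = field(default_factory=dict)

    def is_sign_epistatic(self, m: Mutation | str) -> bool:
        return str(m) in self.sign_epistatic

    def is_synergistic(self, pair: Variant | str) -> bool:
        return str(pair) in self.synergistic_pairs

    def to_json(self) -> str:
        def obs(o: EffectObservation):
            return {"background": str(o.background),
                    "combined": str(o.combined),
                    "effect": o.effect}
        return json.dumps({
            "delta": self.delta,
            "sign_epistatic": {
                m: {**info, "observations": [obs(o) for o in info["observations"]]}
                for m, info in self.sign_epistatic.items()
            },
            "synergistic_pairs": self.synergistic_pairs,
            "effects": {m: [obs(o) for o in v] for m, v in self.effects.items()},
        }, indent=2)

    def __str__(self) -> str:
        lines = [f"Epistasis report (delta = {self.delta} degC)"]
        if self.sign_epistatic:
            lines.append("sign-epistatic mutations:")
            for m, info in self.sign_epistatic.items():
                lines.append(
                    f"  {m}: effects from {info['min_effect']:+.2f} "
                    f"to {info['max_effect']:+.2f} degC over "
                    f"{info['n_backgrounds']} backgrounds"
                )
        else:
            lines.append("sign-epistatic mutations: none")
        if self.synergistic_pairs:
            lines.append("synergistic pairs (WT background):")
            for pair, info in self.synergistic_pairs.items():
                lines.append(f"  {pair}: epsilon = {info['epsilon']:+.2f} degC")
        else:
            lines.append("synergistic pairs: none")
        return "\n".join(lines)


def tm_table(data: Iterable[VariantRecord] | Mapping[str, float]) -> dict[str, float]:
    """Index Tm labels by canonical variant string (replicates averaged)."""
    if isinstance(data, Mapping):
        return dict(data)
    sums: dict[str, list[float]] = {}
    variants: dict[str, Variant] = {}
    for r in data:
        if r.tm is None:
            continue
        key = str(r.variant)
        sums.setdefault(key, []).append(r.tm)
        variants[key] = r.variant
    return {k: sum(v) / len(v) for k, v in sums.items()}


def _variant_index(data: Iterable[VariantRecord]) -> dict[str, Variant]:
    return {str(r.variant): r.variant for r in data if r.tm is not None}


def background_effects(
    data: Sequence[VariantRecord],
    target: Mutation | Sequence[Mutation] | Variant,
) -> list[EffectObservation]:
    """All measured effects of adding ``target`` to any labeled background.

    One observation per pair (B, B u target) where both variants carry Tm
    labels; backgrounds may be any order including WT.
    """
    target_muts = _as_mutations(target)
    if not target_muts:
        raise ValueError("target mutation set is empty")
    labels = tm_table(data)
    index = _variant_index(data)
    target_positions = {m.position for m in target_muts}
    out = []
    for key, bg in index.items():
        if any(p in target_positions for p in bg.positions):
            continue
        combined = bg.union(target_muts)
        ckey = str(combined)
        if ckey in labels:
            out.append(EffectObservation(
                target=target_muts,
                background=bg,
                effect=labels[ckey] - labels[key],
            ))
    return out


def _as_mutations(target) -> tuple[Mutation, ...]:
    if isinstance(target, Mutation):
        return (target,)
    if isinstance(target, Variant):
        return target.mutations
    return tuple(sorted(target, key=lambda m: m.position))


def epistasis_score(
    data: Sequence[VariantRecord] | Mapping[str, float],
    S: Sequence[Mutation] | Variant,
    background: Variant = WILD_TYPE,
) -> float:
    """Deviation from additivity of mutation set S in a background (degC).

    Requires labels for the background, the background plus each single of S,
    and the background plus all of S; raises :class:`MissingDataError`
    listing absent variants rather than imputing them.
    """
    muts = _as_mutations(S)
    labels = data if isinstance(data, Mapping) else tm_table(data)
    needed = {
        str(background): None,
        str(background.union(muts)): None,
    }
    for m in muts:
        needed[str(background.union((m,)))] = None
    missing = [k for k in needed if k not in labels]
    if missing:
        raise MissingDataError(missing)
    y_b = labels[str(background)]
    additive = y_b + sum(labels[str(background.union((m,)))] - y_b for m in muts)
    return labels[str(background.union(muts))] - additive


def classify_epistasis(
    data: Sequence[VariantRecord],
    delta: float = 0.3,
    mutations: Sequence[Mutation] | None = None,
) -> EpistasisReport:
    """Scan a labeled dataset for sign-epistatic mutations and synergistic pairs.

    ``mutations`` restricts the scan; by default every mutation appearing in
    the dataset is examined.  Pairs are tested for synergy in the wild-type
    background only (epsilon > +delta); pairs whose required intermediates are
    unlabeled are skipped (not evaluable), never imputed.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    labels = tm_table(data)
    index = _variant_index(data)
    if mutations is None:
        seen: dict[str, Mutation] = {}
        for v in index.values():
            for m in v.mutations:
                seen[str(m)] = m
        mutations = [seen[k] for k in sorted(seen)]

    report = EpistasisReport(delta=delta)
    for m in mutations:
        obs = background_effects(data, m)
        if not obs:
            continue
        report.effects[str(m)] = obs
        effs = [o.effect for o in obs]
        if max(effs) > delta and min(effs) < -delta:
            report.sign_epistatic[str(m)] = {
                "min_effect": min(effs),
                "max_effect": max(effs),
                "n_backgrounds": len(obs),
                "observations": obs,
            }

    for a, b in itertools.combinations(mutations, 2):
        if a.position == b.position:
            continue
        try:
            eps = epistasis_score(labels, (a, b))
        except MissingDataError:
            continue
        if eps > delta:
            pair = str(Variant((a, b)))
            report.synergistic_pairs[pair] = {
                "epsilon": eps,
                "background": "WT",
                "supporting": [str(Variant((a,))), str(Variant((b,))),
                               str(Variant((a, b)))],
            }
    return report


def mutation_frequency(
    collections: Sequence[Sequence[Variant]],
    m: Mutation,
) -> list[tuple[int, int]]:
    """(count, total) of variants containing ``m`` in each collection.

    Tracks how often a mutation is carried through successive design rounds,
    e.g. the rising frequency of a mutation whose benefit only shows in
    multi-mutation backgrounds.
    """
    out = []
    for coll in collections:
        if not coll:
            raise ValueError("collections must be non-empty")
        count = sum(1 for v in coll if m in v)
        out.append((count, len(coll)))
    return out


def pair_frequency(
    collections: Sequence[Sequence[Variant]],
    pair: Sequence[Mutation],
) -> list[tuple[int, int]]:
    """(count, total) of variants containing every mutation of ``pair``."""
    out = []
    for coll in collections:
        if not coll:
            raise ValueError("collections must be non-empty")
        count = sum(1 for v in coll if v.contains_all(pair))
        out.append((count, len(coll)))
    return out


def effects_to_dataframe(report: EpistasisReport):
    """Flatten the per-mutation effect observations to a tidy table (CSV-ready)."""
    import pandas as pd

    rows = []
    for m, obs in report.effects.items():
        for o in obs:
            rows.append({
                "mutation": m,
                "background": str(o.background),
                "combined": str(o.combined),
                "effect_celsius": o.effect,
                "background_order": o.background.order,
            })
    return pd.DataFrame(rows)
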