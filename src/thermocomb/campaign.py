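"""The iterative design campaign: score, filter, select, measure, retrain.

One round of the loop: (1) fit the thermostability regression head and the
activity discriminant head on all accumulated labels; (2) score every variant
in the combinatorial space; (3) apply the activity acceptability gate (hard
filter before ranking); (4) select a batch — either stratified by mutation
count (e.g. the top performers among 5-9-mutation variants) or the flat global
top of the ranking; (5) query the measurement oracle and fold the new labels
back into the training set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .encoders import EncoderBackend, OneHotEncoder
from .predictor import (
    HeadConfig,
    StabilityModel,
    StabilityResults,
    VariantRecord,
)
from .variants import CandidateSet, Variant, enumerate_combinations, parse_variant

logger = logging.getLogger(__name__)


@dataclass
class SelectionPolicy:
    """How a round's batch is picked from the ranked, activity-filtered table.

    Stratified mode takes ``per_stratum_quota`` top variants per mutation
    count in ``orders``; flat mode takes the global top ``batch_size``.
    Ties on equal predicted score break toward fewer mutations, then the
    canonical variant string.
    """

    batch_size: int = 25
    stratify_by_order: bool = False
    orders: tuple[int, ...] | None = None
    per_stratum_quota: int | None = None
    activity_threshold: float = 60.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.stratify_by_order:
            if not self.orders:
                raise ValueError("stratified policy needs an order range")
            quota = self.per_stratum_quota
            if quota is None:
                quota, rem = divmod(self.batch_size, len(self.orders))
                if rem:
                    raise ValueError(
                        "batch size must divide evenly over strata or set per_stratum_quota"
                    )
                object.__setattr__(self, "per_stratum_quota", quota)
            elif quota * len(self.orders) != self.batch_size:
                raise ValueError("per-stratum quotas must sum to batch size")


@dataclass
class RoundResult:
    """Outcome of one design round."""

    round_index: int
    selected: pd.DataFrame              # variant, order, tm_score, probability
    measured: list[VariantRecord] = field(default_factory=list)
    training_size: int = 0              # records the heads were fitted on this round
    median_predicted_gain: float | None = None

    @property
    def best_measured_tm(self) -> float | None:
        tms = [r.tm for r in self.measured if r.tm is not None]
        return max(tms) if tms else None


def score_space(
    results_tm: StabilityResults,
    results_act: StabilityResults,
    cs: CandidateSet,
    policy: SelectionPolicy | None = None,
    orders: Sequence[int] | None = None,
    cap: int = 24,
) -> pd.DataFrame:
    """Score every variant in the combinatorial space of ``cs``.

    Returns a table sorted by predicted Tm descending with columns
    ``variant, order, tm_score, acceptable, probability``.  Variants failing
    the activity gate keep their row (flag False) but are excluded from
    ranking by :func:`select_batch`.
    """
    policy = policy or SelectionPolicy()
    stream = list(enumerate_combinations(cs, orders=orders, cap=cap))
    tm_scores = results_tm.predict_tm_score(iter(stream))
    act = results_act.predict_activity_acceptable(iter(stream))
    df = pd.DataFrame({
        "variant": [str(v) for v, _ in tm_scores],
        "order": [v.order for v, _ in tm_scores],
        "tm_score": [s for _, s in tm_scores],
        "acceptable": [flag for _, flag, _ in act],
        "probability": [p for _, _, p in act],
    })
    df = df.sort_values(
        ["tm_score", "order", "variant"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df


def select_batch(
    ranked: pd.DataFrame,
    policy: SelectionPolicy,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Pick the round's batch from a scored table.

    Applies the acceptability gate, drops previously measured variants, and
    fills either per-order strata or the flat top of the ranking.  A stratum
    with too few acceptable candidates is part-filled with a logged warning.
    """
    exclude = exclude or set()
    pool = ranked[ranked["acceptable"] & ~ranked["variant"].isin(exclude)]
    pool = pool.sort_values(
        ["tm_score", "order", "variant"], ascending=[False, True, True]
    )
    if pool.empty:
        raise ValueError("no acceptable candidates remain after exclusions")

    if policy.stratify_by_order:
        parts = []
        for k in policy.orders:
            stratum = pool[pool["order"] == k].head(policy.per_stratum_quota)
            if len(stratum) < policy.per_stratum_quota:
                logger.warning(
                    "stratum order=%d has %d acceptable candidates for quota %d",
                    k, len(stratum), policy.per_stratum_quota,
                )
                warnings.warn(
                    f"stratum order={k}: only {len(stratum)} candidates for "
                    f"quota {policy.per_stratum_quota}", stacklevel=2,
                )
            parts.append(stratum)
        batch = pd.concat(parts)
    else:
        batch = pool.head(policy.batch_size)
    return batch.reset_index(drop=True)


# ---------------------------------------------------------------------------
# measurement oracles
# ---------------------------------------------------------------------------


class MeasurementOracle:
    """Source of post-hoc labels for selected variants."""

    def measure(self, variants: Sequence[Variant], round_index: int) -> list[VariantRecord]:
        raise NotImplementedError


class LandscapeOracle(MeasurementOracle):
    """In-silico oracle backed by a synthetic landscape with known truth."""

    def __init__(self, landscape, noise_sd: float | None = None, seed: int = 0):
        self.landscape = landscape
        self.noise_sd = landscape.spec.noise_sd if noise_sd is None else noise_sd
        self.rng = np.random.default_rng(seed)

    def measure(self, variants, round_index):
        return [
            VariantRecord(
                variant=v,
                tm=self.landscape.tm(v) + self.rng.normal(0.0, self.noise_sd),
                relative_activity=max(0.0, self.landscape.activity(v)),
                round=round_index,
            )
            for v in variants
        ]


class CsvRoundTripOracle(MeasurementOracle):
    """Interactive stub: writes a measurement-request CSV and reads answers back.

    ``measure`` writes ``requests_round<k>.csv`` (column ``variant``) into the
    work directory and expects ``measurements_round<k>.csv`` in the
    labeled-table format to already exist (e.g. filled in by a previous
    wet-lab cycle); otherwise it raises, leaving the request file in place.
    """

    def __init__(self, workdir, wild_type: str):
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.wild_type = wild_type

    def measure(self, variants, round_index):
        req = self.workdir / f"requests_round{round_index}.csv"
        pd.DataFrame({"variant": [str(v) for v in variants]}).to_csv(req, index=False)
        answer = self.workdir / f"measurements_round{round_index}.csv"
        if not answer.exists():
            raise FileNotFoundError(
                f"wrote {req}; provide measurements in {answer} and rerun"
            )
        from .predictor import records_from_dataframe
        df = pd.read_csv(answer)
        records = records_from_dataframe(df, self.wild_type)
        for r in records:
            r.round = round_index
        return records


# ---------------------------------------------------------------------------
# the campaign driver
# ---------------------------------------------------------------------------


def run_campaign(
    initial: Sequence[VariantRecord],
    cs: CandidateSet,
    oracle: MeasurementOracle,
    rounds: int,
    cfg_tm: HeadConfig,
    cfg_act: HeadConfig | None = None,
    policies: SelectionPolicy | Sequence[SelectionPolicy] | None = None,
    backend: EncoderBackend | None = None,
    seed: int = 0,
    audit_path=None,
) -> list[RoundResult]:
    """Run ``rounds`` iterations of retrain -> score -> select -> measure.

    ``policies`` may be a single policy (reused each round) or one per round.
    Selected sets are disjoint across rounds and from all training data.  An
    audit log (seeds, configs, per-round selections and measurements) is
    returned via the result objects and optionally persisted as JSON.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if rounds == 0:
        return []
    if cfg_act is None:
        cfg_act = HeadConfig(**{**cfg_tm.__dict__, "task": "discriminant"})
    if policies is None:
        policies = SelectionPolicy()
    if isinstance(policies, SelectionPolicy):
        policies = [policies] * rounds
    if len(policies) != rounds:
        raise ValueError("need one policy per round")
    backend = backend or OneHotEncoder()

    data = list(initial)
    measured_keys = {str(r.variant) for r in data}
    results: list[RoundResult] = []
    audit: list[dict] = []
    prev_median_score = None

    for k in range(1, rounds + 1):
        cfg_tm_k = HeadConfig(**{**cfg_tm.__dict__, "seed": cfg_tm.seed + k})
        cfg_act_k = HeadConfig(**{**cfg_act.__dict__, "seed": cfg_act.seed + k})
        res_tm = StabilityModel(data, cs.wild_type, backend, cfg_tm_k).fit()
        res_act = StabilityModel(data, cs.wild_type, backend, cfg_act_k).fit()

        policy = policies[k - 1]
        ranked = score_space(res_tm, res_act, cs, policy)
        batch = select_batch(ranked, policy, exclude=measured_keys)
        selected_variants = [parse_variant(s, cs.wild_type) for s in batch["variant"]]

        new_records = oracle.measure(selected_variants, round_index=k)
        if not new_records:
            raise RuntimeError(f"oracle returned no measurements in round {k}")

        median_score = float(batch["tm_score"].median())
        gain = None if prev_median_score is None else median_score - prev_median_score
        prev_median_score = median_score

        rr = RoundResult(
            round_index=k,
            selected=batch,
            measured=new_records,
            training_size=len(data),
            median_predicted_gain=gain,
        )
        results.append(rr)
        audit.append({
            "round": k,
            "seed_tm": cfg_tm_k.seed,
            "seed_act": cfg_act_k.seed,
            "training_size": len(data),
            "policy": policy.__dict__ | {"orders": list(policy.orders or [])},
            "selected": batch.to_dict(orient="records"),
            "measured": [
                {"variant": str(r.variant), "tm": r.tm,
                 "relative_activity": r.relative_activity, "round": r.round}
                for r in new_records
            ],
            "median_predicted_score": median_score,
            "median_predicted_gain": gain,
        })

        data.extend(new_records)
        measured_keys.update(str(r.variant) for r in new_records)

    if audit_path is not None:
        Path(audit_path).write_text(json.dumps(audit, indent=2))
    return results
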