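"""End-to-end observer-study orchestration.

Runs the full two-dataset design: compose a high- and a low-variation
50-scan dataset from a simulated pool, have every observer rate both
datasets with both methods (a pairwise-comparison ranking session and a
randomized-order Likert pass), assemble the ratings matrices, and
compute the agreement tables —

* interobserver: one 50 x k matrix per (dataset, method), average-
  measures two-way random absolute-agreement ICC;
* intraobserver: one 25 x 2 matrix per (observer, method) built from
  the original scans present in both datasets (rated twice), single-
  measures ICC.  PC entries are the raw full-session ranks (1-50), not
  re-ranked among the 25 originals.

Every source of randomness (latent pool, patient exclusion, dataset
composition, observer percepts, presentation sides and orders) is
derived from ``master_seed`` through a numpy ``SeedSequence`` spawn
tree, so a study is a pure function of its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .icc import ICCResult, RatingsMatrix, icc_agreement
from .ranking import ComparisonSession, fj_rank
from .simulate import (
    LatentQualityModel,
    ObserverModel,
    ScanSpec,
    compose_dataset,
    default_observer_panel,
    generate_scan_pool,
    simulate_choice,
    simulate_likert,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "interobserver_matrix",
    "intraobserver_matrix",
]

METHODS = ("pc", "likert")
DATASETS = ("high", "low")


@dataclass(frozen=True)
class StudyConfig:
    n_patients: int = 30
    n_excluded: int = 5
    observers: tuple[ObserverModel, ...] = field(
        default_factory=lambda: tuple(default_observer_panel(6))
    )
    quality_model: LatentQualityModel = field(default_factory=LatentQualityModel)
    profiles: Mapping[str, "str | Mapping"] = field(
        default_factory=lambda: {"high": "high", "low": "low"}
    )
    dataset_order: tuple[str, ...] = DATASETS
    master_seed: int = 0

    def __post_init__(self):
        if self.n_patients - self.n_excluded < 2:
            raise ValidationError("need at least 2 patients after exclusion")
        if len(self.observers) < 2:
            raise ValidationError("need at least 2 observers")
        if sorted(self.dataset_order) != sorted(DATASETS):
            raise ValidationError(f"dataset_order must be a permutation of {DATASETS}")


@dataclass
class StudyResult:
    config: StudyConfig
    datasets: dict  # dataset -> list[ScanSpec]
    sessions: dict  # (observer_id, dataset) -> ComparisonSession
    likert_logs: dict  # (observer_id, dataset) -> DataFrame(order, scan_id, score)
    inter_matrices: dict  # (dataset, method) -> RatingsMatrix (50 x k)
    intra_matrices: dict  # (observer_id, method) -> RatingsMatrix (25 x 2)
    inter_icc: dict  # (dataset, method) -> ICCResult (average measures)
    intra_icc: dict  # (observer_id, method) -> ICCResult (single measures)

    @property
    def observer_ids(self) -> list[str]:
        return [f"observer_{i+1}" for i in range(len(self.config.observers))]

    def inter_icc_table(self) -> pd.DataFrame:
        rows = []
        for (ds, method), r in sorted(self.inter_icc.items()):
            rows.append({
                "dataset": ds, "method": method, "measures": r.measures,
                "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
            })
        return pd.DataFrame(rows)

    def intra_icc_table(self) -> pd.DataFrame:
        rows = []
        for (obs, method), r in sorted(self.intra_icc.items()):
            rows.append({
                "observer": obs, "method": method, "measures": r.measures,
                "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
            })
        return pd.DataFrame(rows)


def interobserver_matrix(scores: Mapping[str, Mapping[str, float]]) -> RatingsMatrix:
    """Assemble per-observer scores for one dataset+method into an
    n_scans x k_observers matrix (rows sorted by scan_id).

    ``scores`` maps observer_id -> {scan_id: score}.  All observers must
    have scored the identical scan set.
    """
    if len(scores) < 2:
        raise ValidationError("need at least 2 observers")
    observers = sorted(scores)
    scan_sets = {obs: set(scores[obs]) for obs in observers}
    reference = scan_sets[observers[0]]
    for obs in observers[1:]:
        if scan_sets[obs] != reference:
            diff = scan_sets[obs] ^ reference
            raise AlignmentError(
                f"observer {obs} scored a different scan set; "
                f"symmetric difference: {sorted(diff)}",
                difference=diff,
            )
    scans = sorted(reference)
    values = np.array([[scores[obs][s] for obs in observers] for s in scans])
    return RatingsMatrix(values, subject_ids=scans, rater_ids=observers)


def intraobserver_matrix(
    session1_scores: Mapping[str, float],
    session2_scores: Mapping[str, float],
    originals: Sequence[str],
) -> RatingsMatrix:
    """One observer's repeated scores of the original scans: n x 2."""
    missing = [
        s for s in originals
        if s not in session1_scores or s not in session2_scores
    ]
    if missing:
        raise AlignmentError(
            f"originals absent from a session: {sorted(missing)}",
            difference=set(missing),
        )
    scans = sorted(originals)
    values = np.array([[session1_scores[s], session2_scores[s]] for s in scans])
    return RatingsMatrix(values, subject_ids=scans, rater_ids=["session1", "session2"])


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) % (2**31)


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the whole design and return all artifacts and ICC tables."""
    root = np.random.SeedSequence(config.master_seed)
    ss_pool, ss_excl, ss_high, ss_low, ss_obs = root.spawn(5)

    model = replace(config.quality_model, seed=_seed_int(ss_pool))
    pool = generate_scan_pool(config.n_patients, model)

    patients = sorted({s.patient_id for s in pool})
    rng_excl = np.random.default_rng(ss_excl)
    excluded = set(
        rng_excl.choice(patients, size=config.n_excluded, replace=False).tolist()
    )
    kept_pool = [s for s in pool if s.patient_id not in excluded]
    n_included = config.n_patients - config.n_excluded

    datasets = {
        "high": compose_dataset(
            kept_pool, config.profiles["high"], n_included, seed=_seed_int(ss_high)
        ),
        "low": compose_dataset(
            kept_pool, config.profiles["low"], n_included, seed=_seed_int(ss_low)
        ),
    }
    originals = sorted(
        {s.scan_id for s in datasets["high"] if s.is_original}
        & {s.scan_id for s in datasets["low"] if s.is_original}
    )

    sessions: dict = {}
    likert_logs: dict = {}
    obs_children = ss_obs.spawn(len(config.observers))
    for i, obs_model in enumerate(config.observers):
        obs_id = f"observer_{i+1}"
        ds_seeds = obs_children[i].spawn(len(config.dataset_order))
        for j, ds in enumerate(config.dataset_order):
            scans = datasets[ds]
            by_id = {s.scan_id: s for s in scans}
            ss_pc, ss_side, ss_lik, ss_order = ds_seeds[j].spawn(4)

            rng_pc = np.random.default_rng(ss_pc)
            session = ComparisonSession(
                sorted(by_id), seed=_seed_int(ss_side)
            )
            while session.status == "pending":
                left, right = session.next_pair()
                session.submit_choice(
                    simulate_choice(obs_model, by_id[left], by_id[right], rng_pc)
                )
            sessions[(obs_id, ds)] = session

            rng_lik = np.random.default_rng(ss_lik)
            order = np.random.default_rng(ss_order).permutation(sorted(by_id))
            likert_logs[(obs_id, ds)] = pd.DataFrame({
                "order": np.arange(1, len(order) + 1),
                "scan_id": order,
                "score": [
                    simulate_likert(obs_model, by_id[s], rng_lik) for s in order
                ],
            })

    observer_ids = [f"observer_{i+1}" for i in range(len(config.observers))]
    inter_matrices, inter_icc = {}, {}
    for ds in DATASETS:
        pc_scores = {
            obs: dict(sessions[(obs, ds)].ranking().rank_of)
            for obs in observer_ids
        }
        lik_scores = {
            obs: dict(zip(likert_logs[(obs, ds)].scan_id, likert_logs[(obs, ds)].score))
            for obs in observer_ids
        }
        for method, scores in (("pc", pc_scores), ("likert", lik_scores)):
            m = interobserver_matrix(scores)
            inter_matrices[(ds, method)] = m
            inter_icc[(ds, method)] = icc_agreement(m, measures="average")

    intra_matrices, intra_icc = {}, {}
    ds1, ds2 = config.dataset_order
    for obs in observer_ids:
        pc1 = sessions[(obs, ds1)].ranking().rank_of
        pc2 = sessions[(obs, ds2)].ranking().rank_of
        lik1 = dict(zip(likert_logs[(obs, ds1)].scan_id, likert_logs[(obs, ds1)].score))
        lik2 = dict(zip(likert_logs[(obs, ds2)].scan_id, likert_logs[(obs, ds2)].score))
        for method, (s1, s2) in (("pc", (pc1, pc2)), ("likert", (lik1, lik2))):
            m = intraobserver_matrix(s1, s2, originals)
            intra_matrices[(obs, method)] = m
            intra_icc[(obs, method)] = icc_agreement(m, measures="single")

    return StudyResult(
        config=config,
        datasets=datasets,
        sessions=sessions,
        likert_logs=likert_logs,
        inter_matrices=inter_matrices,
        intra_matrices=intra_matrices,
        inter_icc=inter_icc,
        intra_icc=intra_icc,
    )
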