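"""Synthetic scan pools, study datasets, and stochastic observers.

No pixels are simulated anywhere in this package.  What matters for a
rating-method study is only the *latent* perceived image quality of each
scan, so a scan is reduced to its acquisition metadata plus one latent
scalar:

    latent_q = beta_current * log(current_pct / 100)
             + beta_recon[recon]
             + u_patient,        u_patient ~ N(0, sigma_patient^2)

i.e. quality is monotone in tube-current fraction (less dose -> more
noise -> worse), shifted by the reconstruction method (filtered
backprojection vs iterative reconstruction strengths 2-4), with a
patient-level random effect for anatomy/habitus.

Observers follow a Thurstone Case V style model.  On every exposure the
observer perceives ``scale * latent_q + bias`` plus fresh Gaussian
noise; a forced choice picks the larger percept, so

    P(left preferred) = Phi(scale * (qL - qR) / (sqrt(2) * sigma_compare)),

and a Likert rating thresholds the percept at four cut-points.  Noise
is drawn per comparison, not per scan, so intransitive choice triples
occur naturally — the realistic failure mode a sorting-based pairwise
protocol must tolerate.  The central-tendency bias of human raters
("hesitant to use 1 and 5") is modeled by a wide middle threshold
interval.

The default study composition mirrors a two-dataset design: a pool of
30 patients x 17 scans (the original 100%-current IR2 scan plus the 16
{60,70,80,90}% x {FBP, IR2, IR3, IR4} reconstructions = 510 scans), from
which a "high-variation" and a "low-variation" 50-scan dataset are
drawn, each containing every included patient's original plus one
non-original scan per patient according to a per-cell composition
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CompositionError, ValidationError

__all__ = [
    "RECON_METHODS",
    "CURRENT_LEVELS",
    "PROFILES",
    "ScanSpec",
    "LatentQualityModel",
    "ObserverModel",
    "generate_scan_pool",
    "compose_dataset",
    "simulate_choice",
    "simulate_likert",
    "default_observer_panel",
    "pool_to_frame",
    "pool_from_frame",
]

RECON_METHODS = ("FBP", "IR2", "IR3", "IR4")
CURRENT_LEVELS = (60, 70, 80, 90, 100)

# Non-original cell counts (recon, current_pct) -> number of scans, for a
# 25-patient dataset.  "high" spreads across all reconstructions and
# currents; "low" concentrates near the original operating point (IR2,
# 90-100%) plus a few IR4 scans.
PROFILES: dict[str, dict[tuple[str, int], int]] = {
    "high": {
        ("FBP", 60): 2, ("FBP", 70): 1, ("FBP", 80): 2, ("FBP", 90): 2,
        ("IR2", 60): 2, ("IR2", 70): 2, ("IR2", 80): 1, ("IR2", 90): 2,
        ("IR3", 60): 2, ("IR3", 70): 2, ("IR3", 80): 2, ("IR3", 90): 1,
        ("IR4", 60): 1, ("IR4", 70): 1, ("IR4", 80): 1, ("IR4", 90): 1,
    },
    "low": {
        ("IR2", 90): 18,
        ("IR4", 60): 1, ("IR4", 70): 3, ("IR4", 80): 1, ("IR4", 90): 2,
    },
}


@dataclass(frozen=True)
class ScanSpec:
    """One scan's identity, acquisition metadata and latent quality."""

    scan_id: str
    patient_id: str
    current_pct: int
    recon: str
    is_original: bool
    latent_q: float

    def __post_init__(self):
        if self.current_pct not in CURRENT_LEVELS:
            raise ValidationError(f"current_pct must be one of {CURRENT_LEVELS}")
        if self.recon not in RECON_METHODS:
            raise ValidationError(f"recon must be one of {RECON_METHODS}")
        if self.is_original != (self.current_pct == 100 and self.recon == "IR2"):
            raise ValidationError(
                "is_original must hold exactly for the 100%-current IR2 scan"
            )


@dataclass(frozen=True)
class LatentQualityModel:
    """Linear latent-quality model standing in for image reconstruction."""

    beta_current: float = 2.0
    beta_recon: Mapping[str, float] = field(
        default_factory=lambda: {"FBP": -1.0, "IR2": 0.0, "IR3": 0.5, "IR4": 1.0}
    )
    sigma_patient: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.sigma_patient < 0:
            raise ValidationError("sigma_patient must be >= 0")
        if self.beta_current < 0:
            raise ValidationError("beta_current must be >= 0 (more dose, not-worse IQ)")
        missing = set(RECON_METHODS) - set(self.beta_recon)
        if missing:
            raise ValidationError(f"beta_recon missing offsets for {sorted(missing)}")


@dataclass(frozen=True)
class ObserverModel:
    """Thurstonian observer: percept = scale*q + bias + noise."""

    scale: float = 1.0
    bias: float = 0.0
    sigma_compare: float = 0.5
    sigma_likert: float = 0.5
    thresholds: tuple[float, float, float, float] = (-1.0, -0.4, 0.4, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.scale < 0:
            raise ValidationError("scale must be >= 0")
        if self.sigma_compare < 0 or self.sigma_likert < 0:
            raise ValidationError("noise SDs must be >= 0")
        t = tuple(self.thresholds)
        if len(t) != 4 or any(t[i] >= t[i + 1] for i in range(3)):
            raise ValidationError("thresholds must be 4 strictly increasing cut-points")
        object.__setattr__(self, "thresholds", t)


def default_observer_panel(k: int = 6) -> list[ObserverModel]:
    """A panel of k observers sharing noise levels but with distinct
    systematic biases (some raters score consistently lower/higher)."""
    if k < 2:
        raise ValidationError("need at least 2 observers")
    biases = np.linspace(-0.5, 0.5, k)
    return [ObserverModel(bias=float(b), seed=i) for i, b in enumerate(biases)]


def generate_scan_pool(
    n_patients: int,
    model: LatentQualityModel = LatentQualityModel(),
    rng: np.random.Generator | None = None,
) -> list[ScanSpec]:
    """All 17 scans per patient: the original (100%, IR2) plus the 16
    simulated {60,70,80,90}% x {FBP,IR2,IR3,IR4} reconstructions.

    30 patients give the full 510-scan pool.  Deterministic given the
    model seed (or an explicitly supplied generator).
    """
    if not isinstance(n_patients, int) or n_patients < 1:
        raise ValidationError(f"n_patients must be a positive integer, got {n_patients!r}")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    pool: list[ScanSpec] = []
    for p in range(1, n_patients + 1):
        pid = f"P{p:03d}"
        u = rng.normal(0.0, model.sigma_patient) if model.sigma_patient > 0 else 0.0
        for current in CURRENT_LEVELS:
            for recon in RECON_METHODS:
                original = current == 100 and recon == "IR2"
                if current == 100 and not original:
                    continue  # the 100% scan exists only as the IR2 original
                q = (
                    model.beta_current * math.log(current / 100.0)
                    + model.beta_recon[recon]
                    + u
                )
                pool.append(
                    ScanSpec(
                        scan_id=f"{pid}_{recon}_{current}",
                        patient_id=pid,
                        current_pct=current,
                        recon=recon,
                        is_original=original,
                        latent_q=float(q),
                    )
                )
    return pool


def compose_dataset(
    pool: Sequence[ScanSpec],
    profile: str | Mapping[tuple[str, int], int] = "high",
    n_patients_included: int = 25,
    seed: int = 0,
) -> list[ScanSpec]:
    """Draw one study dataset: every included patient's original plus
    one non-original per patient, matching a per-cell composition table.

    ``profile`` is ``"high"``/``"low"`` (the default tables in
    :data:`PROFILES`) or an explicit ``{(recon, current_pct): count}``
    mapping.  With 25 patients this yields the canonical 50-scan
    dataset (25 originals + 25 variants).  Deterministic given ``seed``.
    """
    table = PROFILES[profile] if isinstance(profile, str) else dict(profile)
    for (recon, current), cnt in table.items():
        if recon == "IR2" and current == 100:
            raise CompositionError(
                "cell (IR2, 100%) is the original scan; composition tables "
                "cover non-originals only"
            )
        if cnt < 0:
            raise CompositionError(f"negative count for cell ({recon}, {current})")

    by_patient: dict[str, dict[tuple[str, int], ScanSpec]] = {}
    for s in pool:
        by_patient.setdefault(s.patient_id, {})[(s.recon, s.current_pct)] = s
    full = sorted(p for p, scans in by_patient.items() if len(scans) == 17)
    if len(full) < n_patients_included:
        raise CompositionError(
            f"pool has {len(full)} patients with complete 17-scan sets, "
            f"need {n_patients_included}"
        )

    rng = np.random.default_rng(seed)
    patients = list(rng.choice(full, size=n_patients_included, replace=False))

    cells = [c for c, cnt in sorted(table.items()) for _ in range(cnt)]
    if len(cells) < n_patients_included:
        raise CompositionError(
            f"composition table provides {len(cells)} non-original scans, "
            f"need {n_patients_included}"
        )
    if len(cells) > n_patients_included:
        cells = [cells[i] for i in rng.choice(len(cells), n_patients_included, replace=False)]
    rng.shuffle(patients)

    chosen: list[ScanSpec] = []
    for pid, cell in zip(patients, cells):
        scan = by_patient[pid].get(cell)
        if scan is None:
            raise CompositionError(
                f"patient {pid} has no scan for cell ({cell[0]}, {cell[1]}%)"
            )
        chosen.append(scan)
    originals = [by_patient[p][("IR2", 100)] for p in patients]
    return sorted(originals + chosen, key=lambda s: s.scan_id)


def simulate_choice(
    obs: ObserverModel,
    left: ScanSpec,
    right: ScanSpec,
    rng: np.random.Generator,
) -> str:
    """Forced choice between two scans; returns the preferred scan_id.

    Fresh perceptual noise is drawn per side per call, so
    P(left) = Phi(scale*(qL-qR) / (sqrt(2)*sigma_compare)).
    """
    if left.scan_id == right.scan_id:
        raise ValidationError("cannot compare a scan with itself")
    x_left = obs.scale * left.latent_q + obs.bias
    x_right = obs.scale * right.latent_q + obs.bias
    if obs.sigma_compare > 0:
        x_left += rng.normal(0.0, obs.sigma_compare)
        x_right += rng.normal(0.0, obs.sigma_compare)
    if x_left == x_right:  # measure-zero tie; break fairly
        return left.scan_id if rng.integers(2) == 0 else right.scan_id
    return left.scan_id if x_left > x_right else right.scan_id


def simulate_likert(
    obs: ObserverModel,
    scan: ScanSpec,
    rng: np.random.Generator,
) -> int:
    """One 5-point rating (1 very poor ... 5 very good) of one scan."""
    x = obs.scale * scan.latent_q + obs.bias
    if obs.sigma_likert > 0:
        x += rng.normal(0.0, obs.sigma_likert)
    return 1 + int(sum(x > t for t in obs.thresholds))


# -- CSV round trip for pools and datasets ---------------------------------

_POOL_COLUMNS = ["scan_id", "patient_id", "current_pct", "recon", "is_original", "latent_q"]


def pool_to_frame(pool: Sequence[ScanSpec]) -> pd.DataFrame:
    return pd.DataFrame([
        {c: getattr(s, c) for c in _POOL_COLUMNS} for s in pool
    ])


def pool_from_frame(df: pd.DataFrame) -> list[ScanSpec]:
    return [
        ScanSpec(
            scan_id=str(r.scan_id), patient_id=str(r.patient_id),
            current_pct=int(r.current_pct), recon=str(r.recon),
            is_original=bool(r.is_original), latent_q=float(r.latent_q),
        )
        for r in df.itertuples()
    ]
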