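"""Synthetic cohorts of regional gray-matter density samples.

Emulates the statistical structure of a case-control, two-arm treatment
study: patients and healthy controls scanned at baseline and after one
and six weeks of treatment, with per-region gray-matter density samples
from which morphological similarity networks are built downstream.

The generative model is deliberately simple so that every downstream
stage has a known ground truth:

* Each region's density values are drawn from a Gaussian (clipped to
  [0, 1], the range of a tissue probability). Region means live in
  latent community blocks: regions of a community sit close together
  (strong similarity edges), communities sit far apart (weak edges),
  and a few *bridge* regions per community sit halfway to the next
  community, providing the long-range shortcuts that make the
  thresholded similarity network small-world.
* Patients at baseline receive a *regularization* perturbation of
  magnitude ``patient_effect``: all within-community offsets (including
  bridge offsets) shrink toward the community centre, which strengthens
  within-community similarity and weakens the bridges — raising the
  clustering coefficient and the characteristic path length of the
  thresholded network. Over treatment the perturbation decays at
  ``normalization_rate``, more strongly for responders.
* Mania scores (YMRS) start >= 20 and decay; the percent reduction is
  coupled (strength ``coupling``) to each patient's network
  normalization through a shared latent factor, and responder status
  (assigned first) conditions both.
* Responders additionally carry a baseline shift of the bilateral
  insula region means (``response_signal``), a pretreatment marker that
  the prediction stage can recover from baseline connectomes.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``CohortConfig.seed``, so generation is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .regions import INSULA_INDICES

__all__ = [
    "CohortConfig",
    "SubjectProfile",
    "generate_cohort",
    "gaussian_kls",
    "clinical_table",
]

# Internal layout constants (see docs/methods.md for rationale).
_CENTER_LO, _CENTER_HI = 0.25, 0.75       # community centre span
_REGION_SIGMA = 0.05                      # density s.d. within a region
_GAP_STEPS = 4.0                          # boundary gap in units of the within step
_SUBJECT_TRAIT_SD = 0.003                 # per-subject, per-region mean shift
_TIMEPOINT_NOISE_SD = 0.0015              # per-scan mean wobble
_SIGMA_TRAIT_LOG_SD = 0.08                # per-subject log-s.d. jitter
_SHRINK_PER_EFFECT = 0.05                 # offset shrinkage per unit patient_effect


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    Defaults reproduce the reference study conditions: 100 patients and
    63 controls, 90 regions, three scans (baseline, week 1, week 6), a
    50/50 split over two pharmacologically distinct but dynamically
    identical treatment arms.
    """

    n_patients: int = 100
    n_controls: int = 63
    n_regions: int = 90
    n_voxels_per_region: int = 500
    timepoints: tuple[str, ...] = ("baseline", "week1", "week6")
    arm_split: float = 0.5
    community_count: int = 6
    patient_effect: float = 1.0
    normalization_rate: float = 0.8
    responder_fraction: float = 0.55
    coupling: float = 0.6
    response_signal: float = 0.02
    response_signal_regions: tuple[int, ...] = INSULA_INDICES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.n_controls < 0:
            raise ValueError(f"n_controls must be >= 0, got {self.n_controls}")
        if self.n_patients + self.n_controls < 1:
            raise ValueError("cohort must contain at least one subject")
        for name in ("n_regions", "n_voxels_per_region", "community_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count, got {getattr(self, name)}")
        if self.community_count > self.n_regions:
            raise ValueError("community_count cannot exceed n_regions")
        if len(self.timepoints) < 1:
            raise ValueError("timepoints must be a non-empty ordered sequence")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be strictly ordered (no duplicates)")
        for name in ("arm_split", "responder_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("normalization_rate", "coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.patient_effect < 0:
            raise ValueError(f"patient_effect must be nonnegative, got {self.patient_effect}")
        if self.response_signal < 0:
            raise ValueError(f"response_signal must be nonnegative, got {self.response_signal}")
        if self.response_signal_regions == INSULA_INDICES and self.n_regions != 90:
            # default insula indices rescale proportionally for other parcellations
            rescaled = tuple(
                sorted({min(i * self.n_regions // 90, self.n_regions - 1) for i in INSULA_INDICES})
            )
            object.__setattr__(self, "response_signal_regions", rescaled)
        for idx in self.response_signal_regions:
            if not 0 <= idx < self.n_regions:
                raise ValueError(
                    f"response_signal_regions index {idx} outside [0, {self.n_regions})"
                )

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SubjectProfile:
    """One subject at one timepoint: regional samples plus covariates."""

    subject_id: str
    group: str                     # "patient" | "control"
    arm: str                       # "lithium-like" | "quetiapine-like" | "none"
    timepoint: str
    age: float
    sex: str                       # "M" | "F"
    ymrs: int
    cdrs: int
    cgis: int
    responder: bool | None         # None for controls
    region_samples: np.ndarray = field(repr=False)  # (n_regions, n_voxels)

    @property
    def n_regions(self) -> int:
        return self.region_samples.shape[0]


def gaussian_kls(mu1, sigma1, mu2, sigma2):
    """Closed-form KLS between two Gaussians.

    Returns ``exp(-(KL(P||Q) + KL(Q||P)))`` with
    ``KL(N1||N2) = ln(s2/s1) + (s1^2 + (m1-m2)^2) / (2 s2^2) - 1/2``.
    Broadcasts over array inputs. This is the analytic oracle against
    which the kernel-density KLS estimator is validated.
    """
    mu1, sigma1, mu2, sigma2 = map(np.asarray, (mu1, sigma1, mu2, sigma2))
    if np.any(sigma1 <= 0) or np.any(sigma2 <= 0):
        raise ValueError("standard deviations must be positive")
    v1, v2 = sigma1**2, sigma2**2
    d2 = (mu1 - mu2) ** 2
    kl_pq = np.log(sigma2 / sigma1) + (v1 + d2) / (2 * v2) - 0.5
    kl_qp = np.log(sigma1 / sigma2) + (v2 + d2) / (2 * v1) - 0.5
    out = np.exp(-(kl_pq + kl_qp))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# latent region layout


def _region_layout(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Base means decomposed as community centre + offset.

    Region means form a 1-D lattice of communities: within a community
    the core regions are evenly spaced (step ``u``), adjacent
    communities are separated by a gap of ``_GAP_STEPS * u`` crossed by
    one *bridge* region per boundary sitting mid-gap. Nearest-neighbour
    similarity links therefore keep the whole lattice connected at the
    lowest sparsity threshold, while the boundary gap plus bridge carry
    all long-range traffic — the structure whose removal the patient
    perturbation emulates.

    Returns ``(community, centers_per_region, offsets)``.
    """
    R, K = cfg.n_regions, cfg.community_count
    sizes = np.full(K, R // K, dtype=int)
    sizes[: R % K] += 1
    community = np.repeat(np.arange(K), sizes)
    if K == 1:
        centers = np.array([0.5])
        m = sizes[0]
        offsets = np.linspace(-0.05, 0.05, m) if m > 1 else np.zeros(1)
        return community, centers[community], offsets

    centers = np.linspace(_CENTER_LO, _CENTER_HI, K)
    spacing = centers[1] - centers[0]

    offsets = np.empty(R)
    pos = 0
    for c in range(K):
        m = sizes[c]
        has_bridge = c < K - 1 and m >= 2
        n_core = m - int(has_bridge)
        # spacing = 2*W + gap, gap = _GAP_STEPS * u, u = 2*W/(n_core - 1)
        if n_core > 1:
            w = spacing / (2.0 + 2.0 * _GAP_STEPS / (n_core - 1))
            core = np.linspace(-w, w, n_core)
            gap = spacing - 2 * w
        else:
            w = 0.0
            core = np.zeros(n_core)
            gap = spacing
        offsets[pos : pos + n_core] = core
        if has_bridge:
            offsets[pos + n_core] = w + gap / 2.0  # mid-gap bridge
        pos += m
    return community, centers[community], offsets


def _week_of(label: str) -> float:
    digits = "".join(ch for ch in label if ch.isdigit())
    return float(digits) if digits else 0.0


def _normalization_progress(timepoints: Sequence[str]) -> np.ndarray:
    """Fraction of eventual normalization realised at each timepoint.

    Square-root-of-time shape: partial change already at week 1,
    complete (relative to the horizon) at the final scan.
    """
    weeks = np.array([_week_of(t) for t in timepoints])
    horizon = weeks.max() if weeks.max() > 0 else 1.0
    return np.sqrt(weeks / horizon)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig) -> list[SubjectProfile]:
    """Generate all subject-timepoint profiles of a synthetic cohort.

    Patients come first (each subject's timepoints in order), then
    controls. Deterministic for a fixed ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    community, centers, offsets = _region_layout(cfg)
    progress = _normalization_progress(cfg.timepoints)
    n_tp = len(cfg.timepoints)

    # --- patient-level latent variables -----------------------------------
    n_p = cfg.n_patients
    if n_p > 0:
        if n_p >= 2:
            n_resp = int(np.clip(round(cfg.responder_fraction * n_p), 1, n_p - 1))
        else:
            n_resp = int(rng.random() < cfg.responder_fraction)
        responder = np.zeros(n_p, dtype=bool)
        responder[rng.permutation(n_p)[:n_resp]] = True

        n_arm1 = int(round(cfg.arm_split * n_p))
        arm = np.array(["quetiapine-like"] * n_p, dtype=object)
        arm[rng.permutation(n_p)[:n_arm1]] = "lithium-like"

        z = rng.standard_normal(n_p)            # shared latent factor
        e = rng.standard_normal(n_p)            # YMRS-specific noise
        # per-patient eventual normalization fraction of the perturbation
        norm_frac = np.clip(
            np.where(responder, 0.85, 0.45) + 0.15 * z, 0.0, 1.0
        )
        c = cfg.coupling
        mix = c * z + math.sqrt(max(1.0 - c**2, 0.0)) * e
        red6 = np.where(
            responder,
            np.clip(0.68 + 0.12 * mix, 0.50, 0.95),
            np.clip(0.30 + 0.12 * mix, 0.02, 0.49),
        )
    else:
        responder = np.zeros(0, dtype=bool)
        arm = np.zeros(0, dtype=object)
        norm_frac = red6 = np.zeros(0)

    profiles: list[SubjectProfile] = []

    def _draw_subject(
        sid: str,
        group: str,
        arm_i: str,
        responder_i: bool | None,
        shrink_by_tp: np.ndarray,
        signal_by_tp: np.ndarray,
        ymrs_by_tp: np.ndarray,
        cdrs_by_tp: np.ndarray,
    ) -> None:
        age = float(np.clip(rng.normal(14.7, 2.0), 10.0, 17.9))
        sex = "M" if rng.random() < 0.40 else "F"
        trait = rng.normal(0.0, _SUBJECT_TRAIT_SD, cfg.n_regions)
        sigma = _REGION_SIGMA * np.exp(rng.normal(0.0, _SIGMA_TRAIT_LOG_SD, cfg.n_regions))
        for t in range(n_tp):
            mu = centers + offsets * (1.0 - shrink_by_tp[t]) + trait
            mu = mu + rng.normal(0.0, _TIMEPOINT_NOISE_SD, cfg.n_regions)
            if signal_by_tp[t] != 0.0:
                mu = mu.copy()
                mu[list(cfg.response_signal_regions)] += signal_by_tp[t]
            samples = rng.normal(
                mu[:, None], sigma[:, None], (cfg.n_regions, cfg.n_voxels_per_region)
            )
            np.clip(samples, 0.0, 1.0, out=samples)
            ymrs = int(ymrs_by_tp[t])
            profiles.append(
                SubjectProfile(
                    subject_id=sid,
                    group=group,
                    arm=arm_i,
                    timepoint=cfg.timepoints[t],
                    age=age,
                    sex=sex,
                    ymrs=ymrs,
                    cdrs=int(cdrs_by_tp[t]),
                    cgis=int(np.clip(1 + round(ymrs / 8), 1, 7)),
                    responder=responder_i,
                    region_samples=samples,
                )
            )

    # --- patients ----------------------------------------------------------
    for i in range(n_p):
        sid = f"P{i + 1:03d}"
        remaining = 1.0 - cfg.normalization_rate * norm_frac[i] * progress
        shrink = _SHRINK_PER_EFFECT * cfg.patient_effect * remaining
        signal = np.where(
            np.array(cfg.timepoints) == cfg.timepoints[0],
            cfg.response_signal if responder[i] else 0.0,
            0.0,
        )
        ymrs0 = 20 + rng.poisson(8)
        red_t = red6[i] * progress + rng.normal(0.0, 0.03, n_tp) * (progress > 0)
        ymrs_t = np.maximum(np.round(ymrs0 * (1.0 - red_t)), 0)
        ymrs_t[0] = ymrs0
        if n_tp > 1:
            # endpoint score must respect the assigned responder label
            # under the >= 50%-reduction rule, whatever the noise draw
            final_red = red6[i] + float(rng.normal(0.0, 0.03))
            if responder[i]:
                final_red = float(np.clip(final_red, 0.50, 0.95))
                ymrs_t[-1] = math.floor(ymrs0 * (1.0 - final_red))
            else:
                final_red = float(np.clip(final_red, 0.02, 0.49))
                ymrs_t[-1] = min(math.ceil(ymrs0 * (1.0 - final_red)), ymrs0)
        cdrs0 = 30 + rng.poisson(10)
        cdrs_t = np.maximum(
            np.round(cdrs0 * (1.0 - 0.5 * red6[i] * progress)), 17
        )
        _draw_subject(sid, "patient", str(arm[i]), bool(responder[i]), shrink, signal, ymrs_t, cdrs_t)

    # --- controls ----------------------------------------------------------
    zeros = np.zeros(n_tp)
    for i in range(cfg.n_controls):
        sid = f"C{i + 1:03d}"
        ymrs_t = rng.poisson(1.5, n_tp)
        cdrs_t = 17 + rng.poisson(3, n_tp)
        _draw_subject(sid, "control", "none", None, zeros, zeros, ymrs_t, cdrs_t)

    return profiles


def clinical_table(profiles: Sequence[SubjectProfile]):
    """Tidy clinical/demographic table, one row per subject-timepoint."""
    import pandas as pd

    rows = [
        {
            "subject_id": p.subject_id,
            "group": p.group,
            "arm": p.arm,
            "timepoint": p.timepoint,
            "age": p.age,
            "sex": p.sex,
            "ymrs": p.ymrs,
            "cdrs": p.cdrs,
            "cgis": p.cgis,
            "responder": p.responder,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
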