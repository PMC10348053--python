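"""Synthetic FRI cohorts with the structure the analyses assume.

The generator emulates a four-wave (ages 9/13/17/23) fluorosis cohort:
a few hundred participants, three examiners with a duplicate-exam
subset for reliability, FDI-numbered permanent teeth with up to four
scored zones, eruption-dependent missingness (late-erupting teeth
unscored at the first wave), cumulative loss to follow-up, a monotone
latent decline in severity, and examiner misclassification noise.

Zone scores come from a latent-threshold (ordinal probit style) model:
each participant draws a severity propensity, each tooth and zone adds
its own persistent noise, and three increasing cutpoints map the latent
value to a true FRI score of 0–3. The decline enters on the latent
scale, shifting every zone down by ``decline_per_interval`` per
inter-exam interval, so that mean-FRI and generalized-category analyses
both respond to it. Observed scores pass the true score through a
row-stochastic examiner confusion matrix, drawn independently per exam.
With an identity confusion matrix and zero decline, every zone's score
is constant across waves by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .fri_data import (
    BLEACHING_COLUMNS,
    DEFAULT_WAVES,
    CohortDataset,
    ToothGroupName,
    Zone,
    tooth_group_members,
)

__all__ = ["SyntheticParams", "generate_cohort", "preset_ifs_like"]

_BUCCAL_ZONES = (Zone.incisal_third, Zone.middle_third, Zone.cervical_third)

#: Default examiner confusion matrix (rows: true FRI, columns: observed).
#: Mostly-correct scoring with the familiar 0/1 ambiguity of the
#: "questionable" category dominating the error mass.
DEFAULT_CONFUSION = (
    (0.997, 0.003, 0.000, 0.000),
    (0.300, 0.600, 0.100, 0.000),
    (0.030, 0.200, 0.720, 0.050),
    (0.000, 0.020, 0.130, 0.850),
)


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the latent-threshold cohort generator.

    All noise scales are on the latent severity scale (arbitrary units
    anchored by ``zone_thresholds``). ``decline_per_interval`` is the
    downward latent shift applied per inter-exam interval; 0 freezes
    severity in time.
    """

    n_participants: int = 330
    waves: tuple[int, ...] = DEFAULT_WAVES
    latent_severity_sd: float = 1.4
    tooth_sd: float = 0.45
    zone_sd: float = 0.35
    zone_thresholds: tuple[float, float, float] = (0.75, 1.8, 2.9)
    decline_per_interval: float = 0.42
    examiner_confusion: tuple = DEFAULT_CONFUSION
    examiner_drift: float = 0.0
    n_examiners: int = 3
    duplicate_exam_fraction: float = 0.15
    dropout_per_wave: float = 0.05
    bleaching_prevalence: float = 0.25
    opacity_rate: float = 0.01
    severity_linked_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if len(self.waves) < 2:
            raise ValueError("need at least two exam waves")
        cuts = np.asarray(self.zone_thresholds, dtype=float)
        if cuts.size != 3 or np.any(np.diff(cuts) <= 0):
            raise ValueError("zone_thresholds must be 3 strictly increasing cutpoints")
        conf = np.asarray(self.examiner_confusion, dtype=float)
        if conf.shape != (4, 4) or np.any(conf < 0) or not np.allclose(conf.sum(axis=1), 1.0):
            raise ValueError("examiner_confusion must be a row-stochastic 4x4 matrix")
        for name in (
            "duplicate_exam_fraction",
            "dropout_per_wave",
            "bleaching_prevalence",
            "opacity_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("latent_severity_sd", "tooth_sd", "zone_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.decline_per_interval < 0:
            raise ValueError("decline_per_interval must be >= 0")
        if self.examiner_drift < 0:
            raise ValueError("examiner_drift must be >= 0")
        drift_mass = (1 + self.examiner_drift * (len(self.waves) - 1)) * (
            1 - np.diag(conf)
        )
        if np.any(drift_mass > 1):
            raise ValueError(
                "examiner_drift inflates a confusion row beyond probability 1 "
                "at the last wave"
            )
        if self.n_examiners < 2:
            raise ValueError("need at least 2 examiners for duplicate exams")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["waves"] = list(self.waves)
        d["zone_thresholds"] = list(self.zone_thresholds)
        d["examiner_confusion"] = [list(r) for r in np.asarray(self.examiner_confusion)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        d = dict(d)
        if "waves" in d:
            d["waves"] = tuple(d["waves"])
        if "zone_thresholds" in d:
            d["zone_thresholds"] = tuple(d["zone_thresholds"])
        if "examiner_confusion" in d:
            d["examiner_confusion"] = tuple(tuple(r) for r in d["examiner_confusion"])
        return cls(**d)


def preset_ifs_like() -> SyntheticParams:
    """Defaults emulating a fluoride-cohort study at the published scale.

    330 participants before dropout (about 282 complete cases over four
    waves at 5% loss per wave), a moderate latent decline, and enough
    examiner disagreement that reliability is imperfect. Cohorts drawn
    from this preset show baseline generalized-fluorosis prevalence of
    roughly 30–55%, age-23 prevalence of roughly 8–30%, negative
    age–severity gammas in the −0.25 to −0.40 range, and inter-examiner
    kappa that declines across waves as fluorosis becomes rarer.
    """
    return SyntheticParams()


def generate_cohort(params: SyntheticParams) -> CohortDataset:
    """Draw one synthetic cohort; fully reproducible under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    waves = np.asarray(params.waves)
    n_waves = waves.size
    n = params.n_participants

    early = sorted(tooth_group_members(ToothGroupName.early_erupting))
    late = sorted(tooth_group_members(ToothGroupName.late_erupting))
    teeth = np.array(early + late)
    first_wave_idx = np.array([0] * len(early) + [1] * len(late))  # eruption schedule
    zones = np.array([z.value for z in (*_BUCCAL_ZONES, Zone.occlusal_incisal)])
    n_teeth, n_zones = teeth.size, zones.size

    pid = np.array([f"P{i + 1:04d}" for i in range(n)])
    examiners = np.array([f"E{i + 1}" for i in range(params.n_examiners)])

    # persistent latent structure: participant + tooth + zone components
    theta = rng.normal(0.0, params.latent_severity_sd, size=n)
    tooth_u = rng.normal(0.0, params.tooth_sd, size=(n, n_teeth))
    zone_e = rng.normal(0.0, params.zone_sd, size=(n, n_teeth, n_zones))
    latent = theta[:, None, None] + tooth_u[:, :, None] + zone_e

    opacity = rng.random((n, n_teeth, n_zones)) < params.opacity_rate

    # cumulative dropout: participant attends waves 0..last_wave
    last_wave = np.full(n, n_waves - 1)
    for w in range(1, n_waves):
        p_drop = params.dropout_per_wave
        if params.severity_linked_dropout:
            # optional robustness probe: milder cases drop out faster
            p_drop = np.clip(
                p_drop - params.severity_linked_dropout * (theta - theta.mean()), 0, 1
            )
        dropped_now = (last_wave == n_waves - 1) & (rng.random(n) < p_drop)
        last_wave[dropped_now] = w - 1

    primary_examiner = rng.integers(0, params.n_examiners, size=(n, n_waves))
    has_duplicate = rng.random((n, n_waves)) < params.duplicate_exam_fraction
    # the duplicate rater is the next examiner cyclically
    duplicate_examiner = (primary_examiner + 1) % params.n_examiners

    cuts = np.asarray(params.zone_thresholds)
    base_conf = np.asarray(params.examiner_confusion, dtype=float)
    # scoring gets harder at later ages: off-diagonal confusion mass grows
    # by examiner_drift per wave (rows renormalized through the diagonal)
    conf_cdfs = []
    eye = np.eye(4)
    for w in range(n_waves):
        scale = 1.0 + params.examiner_drift * w
        conf_w = eye + scale * (base_conf - eye)
        conf_cdfs.append(np.cumsum(conf_w, axis=1))

    frames = []
    for w in range(n_waves):
        present = last_wave >= w
        scored_teeth = first_wave_idx <= w
        if not present.any() or not scored_teeth.any():
            continue
        p_idx = np.nonzero(present)[0]
        t_idx = np.nonzero(scored_teeth)[0]
        value = latent[np.ix_(p_idx, t_idx)] - w * params.decline_per_interval
        true_fri = np.digitize(value, cuts)  # 0..3
        true_fri[opacity[np.ix_(p_idx, t_idx)]] = 0

        for is_dup in (False, True):
            if is_dup:
                sel = has_duplicate[p_idx, w]
                if not sel.any():
                    continue
                pp = p_idx[sel]
                exam_examiner = duplicate_examiner[pp, w]
                tf = true_fri[sel]
                opac = opacity[np.ix_(pp, t_idx)]
            else:
                pp = p_idx
                exam_examiner = primary_examiner[pp, w]
                tf = true_fri
                opac = opacity[np.ix_(pp, t_idx)]
            u = rng.random(tf.shape)
            observed = (u[..., None] > conf_cdfs[w][tf]).sum(axis=-1)
            observed[opac] = 0  # opacities are recorded as 0 by convention

            npp, ntt = pp.size, t_idx.size
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(pid[pp], ntt * n_zones),
                        "exam_age": waves[w],
                        "examiner_id": np.repeat(
                            examiners[exam_examiner], ntt * n_zones
                        ),
                        "tooth": np.tile(np.repeat(teeth[t_idx], n_zones), npp),
                        "zone": np.tile(zones, npp * ntt),
                        "fri": observed.reshape(-1),
                        "nonfluoride_opacity": opac.reshape(-1),
                        "is_primary": not is_dup,
                    }
                )
            )

    scores = pd.concat(frames, ignore_index=True)

    intervals = [f"{waves[i]}-{waves[i + 1]}" for i in range(n_waves - 1)]
    used = rng.random((n, len(intervals))) < params.bleaching_prevalence
    bleaching = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, len(intervals)),
            "interval": np.tile(intervals, n),
            "used_bleaching": used.reshape(-1),
        }
    )[BLEACHING_COLUMNS]

    return CohortDataset(scores=scores, bleaching=bleaching, waves=tuple(waves))
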