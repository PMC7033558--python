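"""Synthetic behavioural cohorts for the hand-laterality judgement task.

Generates trial tables with the structure the analysis chain expects:
three groups (two-handed controls, acquired amputees, congenital
one-handers), two blocks of 48 mirrored hand images (24 left / 24 right),
easy and hard posture classes, noisy-recording and no-response trials at
configurable rates, and amputee covariates (phantom motor control times,
age at amputation, prosthesis-usage ratings).

The generative core is the racing-simulator model itself: control and
amputee subjects draw their trial outcomes from the two-simulator race,
congenital one-handers from the single-simulator architecture.  Amputees
are given the control architecture because the model covers only controls
and congenitals, while amputees behave control-like empirically; their
phantom-motor times are coupled to their realised mean laterality RT
through a Gaussian copula so the target Spearman correlation is hit in
expectation.
"""

from __future__ import annotations

import io
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .race import HANDS, control_architecture, congenital_architecture, _race_batch

__all__ = ["CohortSpec", "generate_cohort", "worked_fixture", "worked_fixture_csv"]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design and generative parameters of one synthetic cohort.

    Defaults follow the study conditions: group sizes 21/16/17, two
    blocks of 48 images, a 2.8% noisy-recording rate, per-subject
    no-response rates averaging 2% with a 10.4% ceiling, and the published
    model parameters per group.
    """

    n_controls: int = 21
    n_amputees: int = 16
    n_congenital: int = 17
    n_blocks: int = 2
    n_images: int = 48  # 24 per side, mirrored pairs (i, i + 24)

    # generating architectures (published group-level parameters)
    drift_rate: float = 0.1
    control_threshold: float = 0.17
    congenital_threshold: float = 0.138
    bias: float = 0.006
    nondecision_time: float = 0.3
    quit_mean: float = 1.6
    quit_sigma: float = 1.0
    noise_coef: float = 0.1
    # coarser Euler step than the model default: with bridge-corrected
    # crossing detection the absorption bias stays far below the injected
    # trial noise, at a quarter of the simulation cost
    dt: float = 0.004

    # trial-level RT structure
    hard_rt_inflation: float = 1.25  # multiplies decision time of hard images
    rt_noise_sigma: float = 0.15  # log-normal trial noise, log units
    subject_sd: float = 0.08  # subject-level log-RT offset SD
    max_display_time: float = 5.0  # seconds; slower trials become no-response

    # validity flags
    noisy_rate: float = 0.028
    noresponse_mean: float = 0.02
    noresponse_max: float = 0.104

    # amputee covariates
    phantom_target_rho: float = 0.7  # Spearman(phantom time, mean laterality RT)
    phantom_log_mean: float = 3.0  # log-seconds; exp(3) ~ 20 s per 5 cycles
    phantom_log_sd: float = 0.6
    age_range: tuple[int, int] = (25, 60)
    age_at_amputation_range: tuple[int, int] = (17, 45)

    def __post_init__(self) -> None:
        for name in ("noisy_rate", "noresponse_mean", "noresponse_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_controls, self.n_amputees, self.n_congenital) < 2:
            raise ValueError("group sizes must be >= 2")
        if not -1.0 < self.phantom_target_rho < 1.0:
            raise ValueError("phantom_target_rho must be in (-1, 1)")
        if self.n_images % 2:
            raise ValueError("n_images must be even (mirrored pairs)")
        if self.noresponse_mean > self.noresponse_max:
            raise ValueError("noresponse_mean cannot exceed noresponse_max")


def _image_table(spec: CohortSpec) -> pd.DataFrame:
    """Stimulus set: image ids, sides and ground-truth difficulty.

    Images 1..n/2 are left hands, each mirrored by image i + n/2 on the
    right; within each side the first half are easy, the rest hard, so a
    mirror pair always shares a difficulty class.
    """
    half = spec.n_images // 2
    rows = []
    for i in range(1, spec.n_images + 1):
        side = "left" if i <= half else "right"
        within = i if i <= half else i - half
        rows.append(
            {
                "image_id": f"img{i:02d}",
                "stimulus_side": side,
                "difficulty": "easy" if within <= half // 2 else "hard",
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one cohort: trial table, subject covariate table, ground truth.

    All randomness derives from ``seed``; the returned ground-truth record
    (spec + seed + per-subject latents) regenerates the cohort exactly.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    images = _image_table(spec)

    # ---- subjects ----------------------------------------------------
    subj_rows = []
    for group, n, prefix in (
        ("controls", spec.n_controls, "C"),
        ("amputees", spec.n_amputees, "A"),
        ("congenital", spec.n_congenital, "G"),
    ):
        for i in range(1, n + 1):
            sid = f"{prefix}{i:02d}"
            age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
            if group == "controls":
                dom = "right" if rng.random() < 0.7 else "left"
                miss_side = "left" if dom == "right" else "right"
                dominant_side, missing_side = dom, None
            else:
                miss = "left" if rng.random() < 0.75 else "right"
                dominant_side, missing_side, miss_side = None, miss, miss
            subj_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "dominant_side": dominant_side,
                    "missing_side": missing_side,
                    "age": age,
                    "_miss_side": miss_side,
                    "_delta": float(rng.normal(0.0, spec.subject_sd)),
                    "_p_nr": _draw_noresp_rate(spec, rng),
                }
            )
    subjects = pd.DataFrame(subj_rows)

    # ---- trial scaffold ---------------------------------------------
    scaffold = (
        subjects[["subject_id", "group", "_miss_side", "_delta", "_p_nr"]]
        .merge(pd.DataFrame({"block": range(1, spec.n_blocks + 1)}), how="cross")
        .merge(images, how="cross")
    )
    scaffold = scaffold.sort_values(["subject_id", "block", "image_id"], kind="stable").reset_index(
        drop=True
    )
    scaffold["stimulus_hand"] = np.where(
        scaffold["stimulus_side"] == scaffold["_miss_side"], "missing", "intact"
    )

    # ---- model-driven outcomes --------------------------------------
    common = dict(
        drift_rate=spec.drift_rate,
        bias=spec.bias,
        nondecision_time=spec.nondecision_time,
        quit_mean=spec.quit_mean,
        quit_sigma=spec.quit_sigma,
        noise_coef=spec.noise_coef,
        dt=spec.dt,
    )
    arch_two = control_architecture(threshold=spec.control_threshold, **common)
    arch_one = congenital_architecture(threshold=spec.congenital_threshold, **common)

    resp_intact = np.zeros(len(scaffold), dtype=bool)
    rt = np.zeros(len(scaffold), dtype=float)
    two_sim = scaffold["group"].isin(["controls", "amputees"]).to_numpy()
    for arch, arch_mask in ((arch_two, two_sim), (arch_one, ~two_sim)):
        for hand in HANDS:
            sel = arch_mask & (scaffold["stimulus_hand"] == hand).to_numpy()
            n = int(sel.sum())
            if n == 0:
                continue
            ri, rts, _ = _race_batch(arch, hand, n, rng)
            resp_intact[sel] = ri
            rt[sel] = rts

    # decision-time scaling: hard-image inflation, subject offset, trial noise
    ter = spec.nondecision_time
    infl = np.where(scaffold["difficulty"] == "hard", spec.hard_rt_inflation, 1.0)
    noise = np.exp(
        scaffold["_delta"].to_numpy() + rng.normal(0.0, spec.rt_noise_sigma, len(scaffold))
    )
    rt = ter + (rt - ter) * infl * noise

    response_hand = np.where(resp_intact, "intact", "missing")
    no_resp = (rt > spec.max_display_time) | (rng.random(len(scaffold)) < scaffold["_p_nr"])
    noisy = rng.random(len(scaffold)) < spec.noisy_rate

    # map response hands back to sides for the recorded verbal response
    intact_side = np.where(scaffold["_miss_side"] == "left", "right", "left")
    resp_side = np.where(response_hand == "intact", intact_side, scaffold["_miss_side"])
    trials = pd.DataFrame(
        {
            "subject_id": scaffold["subject_id"],
            "group": scaffold["group"],
            "block": scaffold["block"],
            "image_id": scaffold["image_id"],
            "stimulus_side": scaffold["stimulus_side"],
            "response": np.where(no_resp, "none", resp_side),
            "rt": np.where(no_resp, np.nan, np.round(rt, 6)),
            "noisy_recording": noisy,
        }
    )

    # ---- amputee covariates -----------------------------------------
    amp = subjects["group"] == "amputees"
    amp_ids = subjects.loc[amp, "subject_id"].to_numpy()
    mean_rt = (
        trials[(trials["group"] == "amputees") & (trials["response"] != "none")]
        .groupby("subject_id")["rt"]
        .mean()
        .reindex(amp_ids)
        .to_numpy()
    )
    n_amp = amp_ids.size
    # Gaussian copula on the realised mean RT: normal scores of ranks,
    # coupled at the Pearson level that yields the target Spearman rho
    u = (sps.rankdata(mean_rt) - 0.5) / n_amp
    z_rt = sps.norm.ppf(u)
    rho_z = 2.0 * math.sin(math.pi * spec.phantom_target_rho / 6.0)
    z_ph = rho_z * z_rt + math.sqrt(1.0 - rho_z**2) * rng.standard_normal(n_amp)
    phantom = np.exp(spec.phantom_log_mean + spec.phantom_log_sd * z_ph)

    ages = subjects.loc[amp, "age"].to_numpy()
    lo = spec.age_at_amputation_range[0]
    hi = np.minimum(spec.age_at_amputation_range[1], ages - 1)
    age_amp = rng.integers(lo, np.maximum(hi, lo) + 1)
    pal = np.round(rng.uniform(1.0, 5.0, n_amp), 2)
    wear = np.round(np.clip(pal + rng.normal(0.0, 1.0, n_amp), 1.0, 5.0), 2)

    subjects = subjects.drop(columns=["_miss_side"])
    subjects["phantom_motor_rt"] = np.nan
    subjects.loc[amp, "phantom_motor_rt"] = np.round(phantom, 2)
    subjects["age_at_amputation"] = np.nan
    subjects.loc[amp, "age_at_amputation"] = age_amp.astype(float)
    subjects["pal_rating"] = np.nan
    subjects.loc[amp, "pal_rating"] = pal
    subjects["wear_time_rating"] = np.nan
    subjects.loc[amp, "wear_time_rating"] = wear
    subjects = subjects.rename(columns={"_delta": "true_log_rt_offset", "_p_nr": "true_noresponse_rate"})

    truth = {
        "seed": int(seed),
        "spec": asdict(spec),
        "architectures": {"two_sim": arch_two.to_dict(), "one_sim": arch_one.to_dict()},
        "copula_pearson_rho": float(rho_z),
        "subject_latents": {
            sid: {"log_rt_offset": float(d), "noresponse_rate": float(p)}
            for sid, d, p in zip(
                subjects["subject_id"], subjects["true_log_rt_offset"], subjects["true_noresponse_rate"]
            )
        },
    }
    return trials, subjects, truth


def _draw_noresp_rate(spec: CohortSpec, rng: np.random.Generator) -> float:
    """Per-subject no-response rate in [0, max] with the configured mean."""
    if spec.noresponse_mean == 0.0 or spec.noresponse_max == 0.0:
        return 0.0
    frac = spec.noresponse_mean / spec.noresponse_max
    b = (1.0 - frac) / frac  # Beta(1, b) has mean frac
    return float(spec.noresponse_max * rng.beta(1.0, b))


# ---------------------------------------------------------------------------
# Worked fixture: a tiny constructed table with hand-computable outcomes


def worked_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 3-subject, 12-trials-each table for exact regression tests.

    * S1 (control, right-dominant): 10/12 correct by construction.
    * S2 (control, right-dominant): 4/12 no-response trials (33%, above the
      27% exclusion cutoff) and one noisy trial.
    * S3 (congenital, left hand missing): 5/6 hits and 2/6 false alarms
      under the intact-as-signal convention.

    Returns ``(trials, handedness)``; built from literals, no RNG.
    """
    rows: list[tuple] = []

    def add(sid, grp, img, side, resp, rt, noisy=False):
        rows.append((sid, grp, 1, img, side, resp, rt, noisy))

    # S1: left images f01-f06 (nondominant -> "missing"), right f07-f12.
    # Errors on f01 and f07; all other responses correct.
    s1_left_rt = [1.00, 1.02, 1.04, 1.06, 1.08, 1.10]
    s1_right_rt = [0.80, 0.82, 0.84, 0.86, 0.88, 0.90]
    for i, r in enumerate(s1_left_rt, start=1):
        resp = "right" if i == 1 else "left"
        add("S1", "controls", f"f{i:02d}", "left", resp, r)
    for i, r in enumerate(s1_right_rt, start=7):
        resp = "left" if i == 7 else "right"
        add("S1", "controls", f"f{i:02d}", "right", resp, r)

    # S2: f01-f04 no response; f05 noisy; f06-f12 valid and correct.
    for i in range(1, 5):
        add("S2", "controls", f"f{i:02d}", "left", "none", float("nan"))
    add("S2", "controls", "f05", "left", "left", 1.00, noisy=True)
    add("S2", "controls", "f06", "left", "left", 1.05)
    for i, r in zip(range(7, 13), [0.95, 0.97, 0.99, 1.01, 1.03, 1.07]):
        add("S2", "controls", f"f{i:02d}", "right", "right", r)

    # S3: intact = right. Right images: 5 "right" responses (hits) + 1 "left".
    # Left images: 4 "left" (correct rejections) + 2 "right" (false alarms).
    s3_right = ["right", "right", "right", "right", "right", "left"]
    s3_left = ["left", "left", "left", "left", "right", "right"]
    for i, resp in enumerate(s3_right, start=7):
        add("S3", "congenital", f"f{i:02d}", "right", resp, 1.20 + 0.02 * (i - 7))
    for i, resp in enumerate(s3_left, start=1):
        add("S3", "congenital", f"f{i:02d}", "left", resp, 1.30 + 0.02 * (i - 1))

    trials = pd.DataFrame(rows, columns=list(
        ("subject_id", "group", "block", "image_id", "stimulus_side", "response", "rt", "noisy_recording")
    ))
    handedness = pd.DataFrame(
        {
            "subject_id": ["S1", "S2", "S3"],
            "group": ["controls", "controls", "congenital"],
            "dominant_side": ["right", "right", None],
            "missing_side": [None, None, "left"],
        }
    )
    return trials, handedness


def worked_fixture_csv() -> str:
    """Canonical CSV serialisation of the worked-fixture trial table."""
    trials, _ = worked_fixture()
    buf = io.StringIO()
    trials.to_csv(buf, index=False, float_format="%.2f", lineterminator="\n")
    return buf.getvalue()
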