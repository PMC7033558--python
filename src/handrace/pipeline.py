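"""Empirical analysis chain for the hand-laterality judgement task.

From trial-level records (one row per trial: subject, group, block, image,
stimulus side, verbal response, RT, noisy-recording flag) to subject- and
group-level summaries:

1. map left/right sides onto intact/missing hands per subject
   (a one-hander's missing side; a control's nondominant side);
2. drop noisy-recording and no-response trials, flagging subjects whose
   no-response rate exceeds an exclusion cutoff;
3. log-transform correct-trial RTs and trim beyond +/-3 SD per
   subject x condition cell;
4. assign easy/hard image difficulty from an independent reference
   group's per-image median RTs (median split over images);
5. signal-detection indices d' and criterion c under the
   intact-hand-as-signal convention;
6. motor-task (finger-thumb opposition) and compound prosthesis-usage
   scores.

Tables are pandas DataFrames throughout.  Expected trial columns:
``subject_id, group, block, image_id, stimulus_side, response, rt,
noisy_recording``; ``map_hands`` adds ``stimulus_hand, response_hand,
correct``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TRIAL_COLUMNS",
    "SDTIndices",
    "DifficultyMap",
    "map_hands",
    "filter_trials",
    "log_trim_rt",
    "assign_difficulty",
    "apply_difficulty",
    "sdt_from_rates",
    "sdt_from_counts",
    "sdt_indices",
    "subject_summary",
    "flag_outlier_subjects",
    "motor_task_score",
    "prosthesis_score",
]

TRIAL_COLUMNS = (
    "subject_id",
    "group",
    "block",
    "image_id",
    "stimulus_side",
    "response",
    "rt",
    "noisy_recording",
)

_SIDES = ("left", "right")


def _opposite(side: str) -> str:
    return "left" if side == "right" else "right"


def map_hands(records: pd.DataFrame, handedness: pd.DataFrame) -> pd.DataFrame:
    """Map left/right stimulus sides and responses onto intact/missing hands.

    ``handedness`` has one row per subject with columns ``subject_id``,
    ``group`` and, depending on group, ``dominant_side`` (controls) or
    ``missing_side`` (one-handers).  For controls the nondominant side
    plays the role of the missing hand; for one-handers it is the missing
    side itself.

    Adds ``stimulus_hand``, ``response_hand`` (``none`` preserved) and
    ``correct`` (nullable boolean, NA for no-response trials).
    """
    h = handedness.set_index("subject_id")
    missing_side: dict[str, str] = {}
    problems: list[str] = []
    for sid, row in h.iterrows():
        if row["group"] == "controls":
            side = row.get("dominant_side")
            side = _opposite(side) if side in _SIDES else None
        else:
            side = row.get("missing_side")
            side = side if side in _SIDES else None
        if side is None:
            problems.append(str(sid))
        else:
            missing_side[sid] = side
    unknown = sorted(set(records["subject_id"]) - set(h.index))
    if problems or unknown:
        raise ValueError(
            "missing handedness metadata for subjects: "
            + ", ".join(sorted(set(problems) | set(unknown)))
        )

    out = records.copy()
    miss = out["subject_id"].map(missing_side)
    out["stimulus_hand"] = np.where(out["stimulus_side"] == miss, "missing", "intact")
    out["response_hand"] = np.where(
        out["response"] == "none",
        "none",
        np.where(out["response"] == miss, "missing", "intact"),
    )
    out["correct"] = pd.array(
        np.where(out["response_hand"] == "none", pd.NA, out["response_hand"] == out["stimulus_hand"]),
        dtype="boolean",
    )
    return out


def filter_trials(
    records: pd.DataFrame, max_noresponse_rate: float = 0.27
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop noisy-recording and no-response trials.

    Returns ``(valid_records, report)`` where the per-subject report lists
    trial counts, noisy and no-response counts, the no-response rate and an
    ``excluded`` flag for subjects at or above ``max_noresponse_rate``
    (default 0.27, the rate at which the study excluded a participant).
    Flagged subjects are reported, not dropped.
    """
    rec = records
    rows = []
    for sid, sub in rec.groupby("subject_id", sort=True):
        n = len(sub)
        n_noisy = int(sub["noisy_recording"].sum())
        n_nr = int((sub["response"] == "none").sum())
        rate = n_nr / n if n else 0.0
        rows.append(
            {
                "subject_id": sid,
                "n_trials": n,
                "n_noisy": n_noisy,
                "n_noresponse": n_nr,
                "noresponse_rate": rate,
                "excluded": rate >= max_noresponse_rate,
            }
        )
    report = pd.DataFrame(rows)
    valid = rec[(~rec["noisy_recording"]) & (rec["response"] != "none")].copy()
    return valid, report


def log_trim_rt(
    records: pd.DataFrame,
    sd_limit: float = 3.0,
    min_cell: int = 3,
    by: Iterable[str] = ("subject_id", "stimulus_hand", "difficulty"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-log transform correct-trial RTs and trim per-cell outliers.

    Only correct, valid trials enter RT analysis; pass the output of
    :func:`filter_trials` restricted upstream or let this function select
    ``correct == True`` rows itself.  Within each subject x condition cell
    trials with ``|log rt - mean| > sd_limit * SD`` are removed in a single
    pass (no re-trimming).  Cells with fewer than ``min_cell`` trials are
    left untouched with a warning.

    Returns ``(trimmed_records_with_log_rt, trim_counts)``.
    """
    by = list(by)
    rec = records[records["correct"].fillna(False).astype(bool)].copy()
    rec["log_rt"] = np.log(rec["rt"].astype(float))
    keep = pd.Series(True, index=rec.index)
    counts = []
    for key, cell in rec.groupby(by, sort=True):
        if len(cell) < min_cell:
            warnings.warn(
                f"cell {key} has {len(cell)} trials (<{min_cell}); trimming skipped",
                stacklevel=2,
            )
            counts.append((*key, 0))
            continue
        lr = cell["log_rt"]
        sd = lr.std(ddof=1)
        if sd == 0:
            counts.append((*key, 0))
            continue
        out = (lr - lr.mean()).abs() > sd_limit * sd
        keep.loc[cell.index[out]] = False
        counts.append((*key, int(out.sum())))
    trim_counts = pd.DataFrame(counts, columns=[*by, "n_trimmed"])
    return rec[keep], trim_counts


@dataclass(frozen=True)
class DifficultyMap:
    """Per-image easy/hard classes from a median split of reference RTs."""

    classes: Mapping[str, str]  # image_id -> "easy" | "hard"
    reference_stat: Mapping[str, float]  # image_id -> per-image median RT (s)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"classes": dict(self.classes), "reference_stat": dict(self.reference_stat)},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "DifficultyMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(classes=d["classes"], reference_stat=d["reference_stat"])


def assign_difficulty(reference_records: pd.DataFrame) -> DifficultyMap:
    """Median split of images into easy/hard from an independent control group.

    The per-image statistic is the median RT over the reference group's
    correct trials (all trials if no ``correct`` column is present).
    Images at or below the across-image median are *easy*; ties at the
    median therefore fall to easy.  An image with no reference trials is
    an error.
    """
    rec = reference_records
    if "correct" in rec.columns:
        rec = rec[rec["correct"].fillna(False).astype(bool)]
    per_image = rec.groupby("image_id")["rt"].median()
    if per_image.isna().any() or len(per_image) == 0:
        raise ValueError("every image needs at least one reference trial")
    all_images = set(reference_records["image_id"])
    missing = sorted(all_images - set(per_image.index))
    if missing:
        raise ValueError(f"images with no usable reference trials: {missing}")
    med = float(per_image.median())
    classes = {img: ("easy" if stat <= med else "hard") for img, stat in per_image.items()}
    return DifficultyMap(classes=classes, reference_stat={k: float(v) for k, v in per_image.items()})


def apply_difficulty(records: pd.DataFrame, dmap: DifficultyMap) -> pd.DataFrame:
    """Attach the ``difficulty`` column from a :class:`DifficultyMap`."""
    out = records.copy()
    out["difficulty"] = out["image_id"].map(dict(dmap.classes))
    if out["difficulty"].isna().any():
        bad = sorted(out.loc[out["difficulty"].isna(), "image_id"].unique())
        raise ValueError(f"images absent from difficulty map: {bad}")
    return out


@dataclass(frozen=True)
class SDTIndices:
    """d' and criterion c with the intact hand as signal.

    Hit: responding "intact" to an intact-hand image.  False alarm:
    responding "intact" to a missing-hand image.  With
    ``c = -(z(H) + z(F)) / 2``, a positive criterion means a tendency to
    over-report "missing hand".
    """

    d_prime: float
    criterion_c: float
    hit_rate: float
    false_alarm_rate: float
    n_signal: int
    n_noise: int


def _clamp_rate(k: int, n: int) -> float:
    """Extreme-rate correction: 0 -> 1/(2N), 1 -> 1 - 1/(2N)."""
    if n <= 0:
        raise ValueError("need at least one trial to form a rate")
    r = k / n
    if r == 0.0:
        return 1.0 / (2 * n)
    if r == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def sdt_from_rates(hit_rate: float, fa_rate: float, n_signal: int = 0, n_noise: int = 0) -> SDTIndices:
    zh = float(sps.norm.ppf(hit_rate))
    zf = float(sps.norm.ppf(fa_rate))
    return SDTIndices(
        d_prime=zh - zf,
        criterion_c=-(zh + zf) / 2.0,
        hit_rate=hit_rate,
        false_alarm_rate=fa_rate,
        n_signal=n_signal,
        n_noise=n_noise,
    )


def sdt_from_counts(n_hit: int, n_signal: int, n_fa: int, n_noise: int) -> SDTIndices:
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need both signal (intact) and noise (missing) trials")
    return sdt_from_rates(_clamp_rate(n_hit, n_signal), _clamp_rate(n_fa, n_noise), n_signal, n_noise)


def sdt_indices(valid_trials: pd.DataFrame) -> SDTIndices:
    """Compute one subject's SDT indices from hand-mapped valid trials."""
    sig = valid_trials[valid_trials["stimulus_hand"] == "intact"]
    noi = valid_trials[valid_trials["stimulus_hand"] == "missing"]
    return sdt_from_counts(
        int((sig["response_hand"] == "intact").sum()),
        len(sig),
        int((noi["response_hand"] == "intact").sum()),
        len(noi),
    )


def subject_summary(
    valid_records: pd.DataFrame,
    trimmed_records: pd.DataFrame,
    trim_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Per subject x hand x difficulty: accuracy, mean log-RT, counts.

    Accuracy is the proportion of correct responses among valid trials in
    the cell; mean log-RT is over correct trials surviving the trim.
    """
    by = ["subject_id", "group", "stimulus_hand", "difficulty"]
    acc = (
        valid_records.groupby(by, sort=True)["correct"]
        .agg(n_valid="count", accuracy="mean")
        .reset_index()
    )
    acc["accuracy"] = acc["accuracy"].astype(float)
    rt = (
        trimmed_records.groupby(by, sort=True)["log_rt"]
        .agg(n_rt="count", mean_log_rt="mean")
        .reset_index()
    )
    out = acc.merge(rt, on=by, how="left").merge(
        trim_counts, on=["subject_id", "stimulus_hand", "difficulty"], how="left"
    )
    out["n_trimmed"] = out["n_trimmed"].fillna(0).astype(int)
    return out


def flag_outlier_subjects(summary: pd.DataFrame, sd_limit: float = 3.0) -> pd.DataFrame:
    """Flag subjects deviating > ``sd_limit`` SD from their group mean.

    Checked per condition (hand x difficulty) and per group, separately
    for accuracy and mean log-RT.  This mirrors an identify-and-report
    rule: flagged subjects are not removed automatically.
    """
    rows = []
    for (grp, hand, diff), cell in summary.groupby(["group", "stimulus_hand", "difficulty"]):
        for col in ("accuracy", "mean_log_rt"):
            vals = cell[col].astype(float)
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            z = (vals - vals.mean()) / sd
            for sid, zi in zip(cell["subject_id"], z):
                if abs(zi) > sd_limit:
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": grp,
                            "stimulus_hand": hand,
                            "difficulty": diff,
                            "measure": col,
                            "z": float(zi),
                        }
                    )
    return pd.DataFrame(rows, columns=["subject_id", "group", "stimulus_hand", "difficulty", "measure", "z"])


def motor_task_score(cycles=None, total: float | None = None, n_cycles: int = 5) -> float:
    """Average time per finger-thumb opposition cycle, in seconds.

    Pass either the individual ``cycles`` durations (must be ``n_cycles``
    of them) or the ``total`` time for all cycles.  The published per-
    subject statistic is the mean over five cycles; a total of 90.3 s
    yields 18.06 s.
    """
    if (cycles is None) == (total is None):
        raise ValueError("pass exactly one of cycles or total")
    if cycles is not None:
        arr = np.asarray(cycles, dtype=float)
        if arr.size != n_cycles or np.any(~np.isfinite(arr)):
            raise ValueError(f"need {n_cycles} finite cycle durations")
        return float(arr.mean())
    if total is None or not np.isfinite(total):
        raise ValueError("total must be finite")
    return float(total) / n_cycles


def prosthesis_score(
    pal_rating, wear_time_rating
) -> tuple[pd.Series, dict]:
    """Compound prosthesis-usage score: sum of within-cohort z-scores.

    Both the activity-log rating and the wear-time rating are z-scored
    across the cohort (sample SD, ddof=1) and summed per subject.  Returns
    the scores and the cohort means/SDs used.
    """
    pal = pd.Series(pal_rating, dtype=float)
    wear = pd.Series(wear_time_rating, dtype=float)
    if len(pal) != len(wear):
        raise ValueError("ratings must be paired")
    meta = {
        "pal_mean": float(pal.mean()),
        "pal_sd": float(pal.std(ddof=1)),
        "wear_mean": float(wear.mean()),
        "wear_sd": float(wear.std(ddof=1)),
    }
    if meta["pal_sd"] == 0 or meta["wear_sd"] == 0 or not np.isfinite(meta["pal_sd"]) or not np.isfinite(meta["wear_sd"]):
        raise ValueError("zero variance in a rating; compound score undefined")
    score = (pal - meta["pal_mean"]) / meta["pal_sd"] + (wear - meta["wear_mean"]) / meta["wear_sd"]
    return score, meta
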