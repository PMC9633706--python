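"""Scoring of the real-vs-DeepFake expert survey.

Each expert labels a mix of real and generated radiographs as real or fake
and additionally rates each image's Kellgren–Lawrence (KL) severity grade.
Because experts may skip items, per-expert metrics use only answered items,
and the headline metric is the balanced accuracy

    BalAcc = ½ · (TP/(TP+FN) + TN/(TN+FP)),

the mean of the two per-class recalls, which is invariant to class
prevalence and reduces to plain accuracy on balanced complete tables.
KL grades collapse to the two-class scheme {0,1} → KL01, {2,3,4} → KL234.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpertScore", "score_expert", "group_summary", "rating_agreement",
    "kl_to_class", "synthetic_responses",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = ["expert_id", "specialty", "image_id", "truth", "call",
                    "truth_kl_class", "rated_kl"]

QUALIFYING_SPECIALTIES = ("orthopedic", "radiologist")


@dataclass(frozen=True)
class ExpertScore:
    """Per-expert survey metrics, as percentages; NaN marks an undefined metric."""

    balanced_accuracy: float
    accuracy_fake: float
    accuracy_real: float
    precision: float
    f1: float
    n_answered: int


def kl_to_class(grade) -> str:
    """Collapse a 0–4 KL grade to the merged two-class scheme."""
    g = int(grade)
    if g not in (0, 1, 2, 3, 4):
        raise ValueError(f"KL grade must be 0..4, got {grade}")
    return "KL01" if g <= 1 else "KL234"


def score_expert(rows: pd.DataFrame, positive_class: str = "fake") -> ExpertScore:
    """Confusion-matrix metrics for one expert's answered items.

    ``positive_class`` selects which label counts as positive for
    precision/recall/F1 (the detection task treats "fake" as positive by
    default). Missing calls are excluded. A zero denominator yields NaN
    (undefined), never 0.
    """
    if positive_class not in ("fake", "real"):
        raise ValueError("positive_class must be 'fake' or 'real'")
    answered = rows[rows["call"].isin(["real", "fake"])]
    if len(answered) == 0:
        raise ValueError("expert has no answered items")
    negative_class = "real" if positive_class == "fake" else "fake"
    truth = answered["truth"]
    call = answered["call"]
    tp = int(((truth == positive_class) & (call == positive_class)).sum())
    fn = int(((truth == positive_class) & (call == negative_class)).sum())
    tn = int(((truth == negative_class) & (call == negative_class)).sum())
    fp = int(((truth == negative_class) & (call == positive_class)).sum())

    def frac(num, den):
        return 100.0 * num / den if den > 0 else math.nan

    recall_pos = frac(tp, tp + fn)
    recall_neg = frac(tn, tn + fp)
    balacc = (recall_pos + recall_neg) / 2.0
    precision = frac(tp, tp + fp)
    if math.isnan(precision) or math.isnan(recall_pos) or precision + recall_pos == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * precision * recall_pos / (precision + recall_pos)
    acc_fake = recall_pos if positive_class == "fake" else recall_neg
    acc_real = recall_neg if positive_class == "fake" else recall_pos
    return ExpertScore(balanced_accuracy=balacc, accuracy_fake=acc_fake,
                       accuracy_real=acc_real, precision=precision, f1=f1,
                       n_answered=len(answered))


_METRICS = ["balanced_accuracy", "accuracy_fake", "accuracy_real", "precision", "f1"]


def per_expert_scores(table: pd.DataFrame, positive_class: str = "fake") -> pd.DataFrame:
    """One scored row per qualifying expert; disqualifying specialties dropped."""
    qualified = table[table["specialty"].isin(QUALIFYING_SPECIALTIES)]
    rows = []
    for (expert, specialty), grp in qualified.groupby(["expert_id", "specialty"]):
        s = score_expert(grp, positive_class=positive_class)
        rows.append({"expert_id": expert, "specialty": specialty,
                     **{m: getattr(s, m) for m in _METRICS},
                     "n_answered": s.n_answered})
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, positive_class: str = "fake") -> pd.DataFrame:
    """Mean (± sample SD) of each metric per specialty, plus an "All" row.

    Means are unweighted over experts. SD uses the n−1 convention; a
    single-expert group reports SD 0 with its n flagging the situation.
    """
    scores = per_expert_scores(table, positive_class=positive_class)
    if scores.empty:
        raise ValueError("no qualifying experts in table")

    def summarize(group_name, frame):
        row = {"group": group_name, "n_experts": len(frame)}
        for m in _METRICS:
            vals = frame[m].dropna().to_numpy()
            row[f"{m}_mean"] = float(vals.mean()) if vals.size else math.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return row

    out = [summarize(spec, grp) for spec, grp in scores.groupby("specialty")]
    out.append(summarize("all", scores))
    return pd.DataFrame(out)


def rating_agreement(table: pd.DataFrame) -> pd.DataFrame:
    """KL-class agreement per group for the four (source × class) cells.

    Per expert and cell (truth ∈ {real, fake} × truth class ∈ {KL01, KL234}),
    the fraction of rated images whose collapsed KL rating matches the truth
    class; missing ratings are excluded per expert, and an expert with no
    ratings in a cell is excluded from that cell's mean. Group value is the
    unweighted mean over experts with sample SD.
    """
    qualified = table[table["specialty"].isin(QUALIFYING_SPECIALTIES)].copy()
    rated = qualified[qualified["rated_kl"].notna()].copy()
    if rated.empty:
        raise ValueError("no KL ratings in table")
    rated["rated_class"] = rated["rated_kl"].map(kl_to_class)
    rated["match"] = rated["rated_class"] == rated["truth_kl_class"]

    per_expert = (rated
                  .groupby(["expert_id", "specialty", "truth", "truth_kl_class"])
                  ["match"].mean().mul(100.0).reset_index(name="agreement"))

    def summarize(group_name, frame):
        rows = []
        for (truth, klc), cell in frame.groupby(["truth", "truth_kl_class"]):
            vals = cell["agreement"].to_numpy()
            rows.append({
                "group": group_name, "source": truth, "kl_class": klc,
                "n_experts": len(vals),
                "agreement_mean": float(vals.mean()),
                "agreement_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            })
        return rows

    out = []
    for spec, grp in per_expert.groupby("specialty"):
        out.extend(summarize(spec, grp))
    out.extend(summarize("all", per_expert))
    return pd.DataFrame(out)


def synthetic_responses(n_orthopedic: int = 5, n_radiologist: int = 10,
                        n_real: int = 30, n_fake: int = 30,
                        detect_accuracy: float = 0.6,
                        rating_accuracy: float = 0.7,
                        missing_rate: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic survey response table for testing.

    Each expert answers the detection question correctly with probability
    ``detect_accuracy`` and rates the KL class correctly with probability
    ``rating_accuracy`` (a wrong rating draws a grade from the opposite
    class); calls go missing independently at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    experts = ([("orto%02d" % i, "orthopedic") for i in range(n_orthopedic)]
               + [("rad%02d" % i, "radiologist") for i in range(n_radiologist)])
    images = []
    for j in range(n_real + n_fake):
        truth = "real" if j < n_real else "fake"
        klc = "KL01" if j % 2 == 0 else "KL234"
        images.append((f"img{j:03d}", truth, klc))

    grades = {"KL01": (0, 1), "KL234": (2, 3, 4)}
    rows = []
    for expert, specialty in experts:
        for image_id, truth, klc in images:
            if rng.random() < missing_rate:
                call = "missing"
            elif rng.random() < detect_accuracy:
                call = truth
            else:
                call = "fake" if truth == "real" else "real"
            target = klc if rng.random() < rating_accuracy else (
                "KL234" if klc == "KL01" else "KL01")
            rated = int(rng.choice(grades[target]))
            rows.append({"expert_id": expert, "specialty": specialty,
                         "image_id": image_id, "truth": truth, "call": call,
                         "truth_kl_class": klc, "rated_kl": rated})
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
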