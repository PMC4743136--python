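"""End-to-end screening sessions and study-level performance accounting.

A session is 12 one-second records of one subject. Every record yields four
decisions (central fixation and focus, per eye); an eye passes a criterion
at session level when at least 2 of the 12 records pass it, and proper
alignment requires simultaneous central fixation of both eyes. A study runs
many subjects against an examiner's gold standard and reports confusion
counts with the screening convention that "positive" means abnormal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DegenerateRecordError, ScanConfig
from .fixation import (
    LDAModel,
    ThresholdModel,
    classify_record,
    evaluate,
    session_decision,
)
from .focus import FD_THRESHOLD, focus_features
from .phss import phss
from .spectral import extract_features, normalize
from .synthesis import FocusState, NoiseSpec, RawRecord, random_eye, synthesize_record

__all__ = ["StudyConfig", "SubjectSpec", "SessionResult", "run_session",
           "simulate_session", "run_study"]

#: Published discriminant coefficients (a0, a1, ...) of the 2/3/4-way fits,
#: carried as instrument defaults; synthetic studies normally recalibrate.
DEFAULT_LDA_COEFFS = {
    2: (0.743, 0.318),
    3: (0.768, 0.056, -0.289),
    4: (0.779, 0.016, -0.283, 0.083),
}


@dataclass
class StudyConfig:
    """Everything needed to acquire and judge a session."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    records_per_session: int = 12
    k_required: int = 2
    cf_method: str = "threshold"  # threshold | lda2 | lda3 | lda4
    cf_theta: float = 0.8750
    lda_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_LDA_COEFFS))
    fd_threshold: float = FD_THRESHOLD
    channel_mode: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_required > self.records_per_session:
            raise ValueError("k_required must not exceed records_per_session")

    def cf_model(self):
        """Decision model implied by ``cf_method`` (unless one is supplied)."""
        if self.cf_method == "threshold":
            return ThresholdModel(theta=self.cf_theta)
        if self.cf_method in ("lda2", "lda3", "lda4"):
            dims = int(self.cf_method[-1])
            return LDAModel.from_a(self.lda_coeffs[dims], dims=dims)
        raise ValueError(f"unknown cf_method {self.cf_method!r}")


@dataclass
class SubjectSpec:
    """Ground truth of one simulated subject.

    ``offset_*`` are fixation offsets in degrees of visual angle (non-zero =
    that eye does not centrally fixate); ``defocus_*`` are dioptric defocus
    values. Gold labels follow from the truth: misalignment when either eye
    is off center, focus failure when either eye exceeds 1 D of defocus.
    """

    subject_id: str = "S0"
    group: str = "normal"  # normal | patient
    offset_L: tuple[float, float] = (0.0, 0.0)
    offset_R: tuple[float, float] = (0.0, 0.0)
    defocus_L_D: float = 0.0
    defocus_R_D: float = 0.0

    @property
    def gold_cf_abnormal(self) -> bool:
        return any(np.hypot(*o) > 0.5 for o in (self.offset_L, self.offset_R))

    @property
    def gold_fd_abnormal(self) -> bool:
        return max(abs(self.defocus_L_D), abs(self.defocus_R_D)) > 1.0


@dataclass
class SessionResult:
    """Per-record decision table plus session-level flags and features."""

    table: pd.DataFrame
    cf_overall: dict[str, bool]
    fd_overall: dict[str, bool]
    alignment_pass: bool
    fd_pass: bool
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "cf_overall": self.cf_overall,
            "fd_overall": self.fd_overall,
            "alignment_pass": self.alignment_pass,
            "fd_pass": self.fd_pass,
            "meta": self.meta,
        }

    def save(self, csv_path: str | Path) -> Path:
        csv_path = Path(csv_path)
        self.table.to_csv(csv_path, index=False)
        csv_path.with_suffix(".summary.json").write_text(
            json.dumps(self.summary(), indent=1, default=str)
        )
        return csv_path


def run_session(records: list[RawRecord], cfg: StudyConfig | None = None,
                model=None) -> SessionResult:
    """Run the full pipeline on exactly ``records_per_session`` records.

    A degenerate eye-record (no carrier power, e.g. a blink) is flagged
    unusable and counts as a failed record in the 2-of-12 numerator while
    the denominator stays at 12 -- conservative toward failing.
    """
    cfg = cfg or StudyConfig()
    if len(records) != cfg.records_per_session:
        raise ValueError(
            f"expected {cfg.records_per_session} records, got {len(records)}"
        )
    model = model if model is not None else cfg.cf_model()
    rows = []
    for i, rec in enumerate(records):
        p = phss(rec)
        feats = extract_features(p, rec.cfg, channel_mode=cfg.channel_mode)
        foc = focus_features(p, rec.cfg)
        row = {"record": i}
        for eye in ("L", "R"):
            try:
                nf = normalize(feats[eye])
                g = foc[eye].goodness
                row[f"usable_{eye}"] = True
                row[f"r_cf_{eye}"] = nf.r_cf
                row[f"goodness_{eye}"] = g
                row[f"cf_{eye}"] = bool(classify_record(nf, model))
                row[f"fd_{eye}"] = bool(g >= cfg.fd_threshold)
            except DegenerateRecordError:
                row[f"usable_{eye}"] = False
                row[f"r_cf_{eye}"] = np.nan
                row[f"goodness_{eye}"] = np.nan
                row[f"cf_{eye}"] = False
                row[f"fd_{eye}"] = False
        rows.append(row)
    table = pd.DataFrame(rows)
    cf_overall = {
        e: session_decision(table[f"cf_{e}"], cfg.k_required, cfg.records_per_session)
        for e in ("L", "R")
    }
    fd_overall = {
        e: session_decision(table[f"fd_{e}"], cfg.k_required, cfg.records_per_session)
        for e in ("L", "R")
    }
    return SessionResult(
        table=table,
        cf_overall=cf_overall,
        fd_overall=fd_overall,
        alignment_pass=cf_overall["L"] and cf_overall["R"],
        fd_pass=fd_overall["L"] and fd_overall["R"],
        meta=records[0].meta.get("subject_meta", {}) if records else {},
    )


def _focus_state(defocus_D: float) -> FocusState:
    # A fixed dioptric error, decoupled from accommodation: cyclopleged state
    # whose demand equals the requested defocus.
    return FocusState(stimulus_vergence_D=0.0, refraction_D=defocus_D,
                      cyclopleged=True)


def simulate_session(spec: SubjectSpec, cfg: StudyConfig | None = None,
                     seed: int = 0) -> list[RawRecord]:
    """Simulate the 12 records of one subject (fresh corneal draw per eye)."""
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(seed)
    eye_L = replace(random_eye(rng), fixation_offset_deg=tuple(spec.offset_L))
    eye_R = replace(random_eye(rng), fixation_offset_deg=tuple(spec.offset_R))
    focus = (_focus_state(spec.defocus_L_D), _focus_state(spec.defocus_R_D))
    return [
        synthesize_record(
            (eye_L, eye_R), focus, noise=cfg.noise, cfg=cfg.scan,
            seed=int(rng.integers(0, 2**31)),
            meta={"record": i, "subject_meta": {"subject_id": spec.subject_id,
                                                "group": spec.group}},
        )
        for i in range(cfg.records_per_session)
    ]


def run_study(subjects: list[SubjectSpec], cfg: StudyConfig | None = None,
              model=None, seed: int = 0) -> dict:
    """Screen a list of simulated subjects and tabulate performance.

    Returns per-subject decisions, per-function confusion counts (CF, FD and
    both combined) and Table-style correctly/incorrectly-identified counts
    per group.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(seed)
    per_subject = []
    for spec in subjects:
        records = simulate_session(spec, cfg, seed=int(rng.integers(0, 2**31)))
        res = run_session(records, cfg, model=model)
        per_subject.append({
            "subject_id": spec.subject_id,
            "group": spec.group,
            "cf_fail": not res.alignment_pass,
            "fd_fail": not res.fd_pass,
            "gold_cf": spec.gold_cf_abnormal,
            "gold_fd": spec.gold_fd_abnormal,
        })
    df = pd.DataFrame(per_subject)
    report = {"subjects": df}
    confusion = {}
    for name, pred, gold in [
        ("CF", df.cf_fail, df.gold_cf),
        ("FD", df.fd_fail, df.gold_fd),
        ("Both", df.cf_fail | df.fd_fail, df.gold_cf | df.gold_fd),
    ]:
        confusion[name] = evaluate(pred.to_numpy(), gold.to_numpy())
    report["confusion"] = confusion
    groups = {}
    for grp, sub in df.groupby("group"):
        correct = ((sub.cf_fail == sub.gold_cf) & (sub.fd_fail == sub.gold_fd)).sum()
        groups[grp] = {"n": int(len(sub)), "CI": int(correct),
                       "ICI": int(len(sub) - correct)}
    report["groups"] = groups
    return report
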