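"""Agreement analysis between automated and manual GA segmentation.

Implements the validation statistics of the study design: per-scan Dice
similarity (DSC) and lesion areas, Pearson r^2 between manual and automated
areas, Bland-Altman bias and limits of agreement, pooled-variance Student
t-tests between the GA-only and GA-with-nAMD strata, a Fisher-z test for
equality of the two strata's correlations, subject-grouped N-fold
cross-validation orchestration, longitudinal area tracking under a fixed
model, and a connected-component diagnostic for lesion coalescence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    ConfigError,
    InsufficientDataError,
    IntegrityError,
    ShapeError,
)
from .net import NetConfig, binarize, build
from .preprocess import NetInput, prepare_inputs, quality_filter
from .profiles import DeviceProfile, get_profile
from .train import TrainConfig, fit, make_grouped_folds, split_train_val
from .types import EnFaceMask, OCTVolume, ScanRecord

__all__ = [
    "EvalReport", "dsc", "area_mm2", "r2", "bland_altman", "ttest",
    "fisher_z_test", "compare_r2_between_strata", "compute_report",
    "cross_validate", "longitudinal_report", "coalescence_diagnostic",
]


def dsc(a: EnFaceMask, b: EnFaceMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks agree perfectly on the absence of GA: DSC = 1.
    """
    ga, gb = np.asarray(a.grid) > 0, np.asarray(b.grid) > 0
    if ga.shape != gb.shape:
        raise ShapeError(f"mask shape mismatch: {ga.shape} vs {gb.shape}")
    na, nb = int(ga.sum()), int(gb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ga & gb).sum()) / (na + nb)


def area_mm2(mask: EnFaceMask) -> float:
    """Lesion area = GA pixel count times en face pixel area."""
    if mask.pixel_area_mm2 is None:
        raise ConfigError("mask has no pixel_area_mm2 metadata")
    return float((np.asarray(mask.grid) > 0).sum()) * mask.pixel_area_mm2


def r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two equal-length samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise InsufficientDataError("r2 needs two equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise InsufficientDataError("correlation undefined for zero-variance sample")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def bland_altman(auto: Sequence[float], manual: Sequence[float]) -> tuple[float, float, float]:
    """Bland-Altman agreement of paired measurements.

    Differences are taken as manual - auto. Returns (bias, loa_low,
    loa_high) with the limits of agreement at bias +/- 1.96 sample standard
    deviations.
    """
    auto = np.asarray(auto, float)
    manual = np.asarray(manual, float)
    if auto.shape != manual.shape or auto.size < 2:
        raise InsufficientDataError("bland_altman needs >= 2 paired measurements")
    d = manual - auto
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance (Student) t-test, two-sided.

    Degenerate guards: zero pooled variance yields p = 1 for equal means and
    p = 0 (t = +/-inf) otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("ttest needs n >= 2 in each group")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df=na + nb - 2))
    return float(t), p


def fisher_z_test(r1: float, n1: int, r2_: float, n2: int) -> float:
    """Two-sided test of equality of two independent Pearson correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    if n1 < 4 or n2 < 4:
        raise InsufficientDataError("fisher z test needs n >= 4 per stratum")
    if abs(r1) >= 1.0 or abs(r2_) >= 1.0:
        raise InsufficientDataError("correlation magnitude 1 is a boundary case")
    z = (math.atanh(r1) - math.atanh(r2_)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return 2.0 * float(stats.norm.sf(abs(z)))


@dataclass
class EvalReport:
    """Cohort-level agreement report."""

    per_scan: pd.DataFrame  # record_id, subject_id, dsc, areas, has_nAMD, fold
    r2: float
    bias_mm2: float
    loa_mm2: tuple[float, float]
    strata: dict[str, dict]  # {"GA_only": {...}, "GA_nAMD": {...}}
    p_dsc: Optional[float]
    p_r2: Optional[float]
    p_r2_method: str
    n_folds: int

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "r2": self.r2,
            "bias_mm2": self.bias_mm2,
            "loa_mm2": list(self.loa_mm2),
            "strata": self.strata,
            "p_dsc": self.p_dsc,
            "p_r2": self.p_r2,
            "p_r2_method": self.p_r2_method,
            "n_folds": self.n_folds,
            "per_scan": self.per_scan.to_dict(orient="records"),
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=1, default=float))

    @property
    def mean_dsc(self) -> float:
        return float(self.per_scan["dsc"].mean())


def compute_report(per_scan: pd.DataFrame, n_folds: int = 0) -> EvalReport:
    """Aggregate a per-scan table into the full agreement report.

    ``per_scan`` columns: record_id, dsc, area_manual_mm2, area_auto_mm2,
    has_nAMD (+ optional subject_id, fold). Strata statistics and their
    p-values are computed when both strata are large enough, else left None.
    """
    req = {"record_id", "dsc", "area_manual_mm2", "area_auto_mm2", "has_nAMD"}
    missing = req - set(per_scan.columns)
    if missing:
        raise ConfigError(f"per-scan table missing columns: {sorted(missing)}")
    manual = per_scan["area_manual_mm2"].to_numpy(float)
    auto = per_scan["area_auto_mm2"].to_numpy(float)
    # a degenerate model (e.g. untrained, all-background) has zero area
    # variance; report NaN correlation rather than failing the whole report
    if len(per_scan) >= 3 and auto.std() > 0 and manual.std() > 0:
        overall_r2 = r2(auto, manual)
    else:
        overall_r2 = float("nan")
    bias, lo, hi = bland_altman(auto, manual)

    strata: dict[str, dict] = {}
    parts = {}
    for name, flag in (("GA_only", False), ("GA_nAMD", True)):
        sub = per_scan[per_scan["has_nAMD"] == flag]
        parts[name] = sub
        entry: dict = {"n": int(len(sub))}
        if len(sub):
            entry["mean_dsc"] = float(sub["dsc"].mean())
        if len(sub) >= 3 and sub["area_manual_mm2"].std() > 0 and sub["area_auto_mm2"].std() > 0:
            entry["r2"] = r2(sub["area_auto_mm2"], sub["area_manual_mm2"])
        strata[name] = entry

    p_dsc = None
    if len(parts["GA_only"]) >= 2 and len(parts["GA_nAMD"]) >= 2:
        _, p_dsc = ttest(parts["GA_only"]["dsc"], parts["GA_nAMD"]["dsc"])
    p_r2 = None
    if "r2" in strata["GA_only"] and "r2" in strata["GA_nAMD"] and \
            strata["GA_only"]["n"] >= 4 and strata["GA_nAMD"]["n"] >= 4:
        r_a = math.sqrt(strata["GA_only"]["r2"])
        r_b = math.sqrt(strata["GA_nAMD"]["r2"])
        if r_a < 1.0 and r_b < 1.0:
            p_r2 = fisher_z_test(r_a, strata["GA_only"]["n"], r_b, strata["GA_nAMD"]["n"])
    return EvalReport(
        per_scan=per_scan.reset_index(drop=True),
        r2=overall_r2,
        bias_mm2=bias,
        loa_mm2=(lo, hi),
        strata=strata,
        p_dsc=p_dsc,
        p_r2=p_r2,
        p_r2_method="fisher-z",
        n_folds=n_folds,
    )


def compare_r2_between_strata(per_scan: pd.DataFrame) -> float:
    """Fisher-z p-value for equality of the strata's area correlations."""
    rs, ns = [], []
    for flag in (False, True):
        sub = per_scan[per_scan["has_nAMD"] == flag]
        rs.append(math.sqrt(r2(sub["area_auto_mm2"], sub["area_manual_mm2"])))
        ns.append(len(sub))
    return fisher_z_test(rs[0], ns[0], rs[1], ns[1])


class _Predictor(Protocol):
    def predict(self, vol: OCTVolume, nir=None) -> EnFaceMask: ...


def cross_validate(
    records: Sequence[ScanRecord],
    net_config: NetConfig,
    train_config: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    profile: Optional[DeviceProfile] = None,
    use_nir: bool = False,
    input_cache: Optional[dict[str, NetInput]] = None,
) -> EvalReport:
    """Subject-grouped N-fold cross-validation of the segmentation network.

    Quality filtering is applied first; each included scan is predicted
    exactly once, by the model of the fold that held it out. Per-scan DSC
    and areas are aggregated into a cohort report. Deterministic per seed.
    """
    devices = {r.device for r in records}
    if len(devices) != 1:
        raise ConfigError(f"cross_validate expects a single-device cohort, got {devices}")
    profile = profile or get_profile(records[0].device)
    included, _ = quality_filter(records)
    if not included:
        raise InsufficientDataError("no records pass the quality filter")
    folds = make_grouped_folds(included, n_folds, seed)
    cache = input_cache if input_cache is not None else {}
    fold_seeds = np.random.SeedSequence(seed).generate_state(n_folds * 2)

    rows = []
    px_area = profile.mask_pixel_area_mm2
    for k in range(n_folds):
        test_recs = folds.records_in_fold(included, k)
        pool = folds.records_not_in_fold(included, k)
        tr_recs, va_recs = split_train_val(pool, train_config.val_fraction,
                                           int(fold_seeds[2 * k]))
        tr = prepare_inputs(tr_recs, profile, use_nir, cache)
        va = prepare_inputs(va_recs, profile, use_nir, cache)
        te = prepare_inputs(test_recs, profile, use_nir, cache)
        net = build(NetConfig(**{**net_config.__dict__,
                                 "seed": int(fold_seeds[2 * k + 1]) % (2 ** 31)}))
        fold_tc = TrainConfig(**{**train_config.__dict__,
                                 "seed": int(fold_seeds[2 * k]) % (2 ** 31)})
        net, _hist = fit(net, tr, va, fold_tc)
        for sample in te:
            prob = net.predict_proba(sample.volume, sample.nir)
            pred = binarize(prob, 0.5, pixel_area_mm2=px_area)
            tgt = sample.target
            rows.append({
                "record_id": sample.record.record_id,
                "subject_id": sample.record.subject_id,
                "fold": k,
                "dsc": dsc(pred, tgt),
                "area_manual_mm2": area_mm2(
                    EnFaceMask(tgt.grid, pixel_area_mm2=px_area, binary=True)),
                "area_auto_mm2": area_mm2(pred),
                "has_nAMD": sample.record.has_nAMD,
            })
    per_scan = pd.DataFrame(rows)
    return compute_report(per_scan, n_folds=n_folds)


def longitudinal_report(records: Sequence[ScanRecord], model: _Predictor,
                        profile: Optional[DeviceProfile] = None) -> pd.DataFrame:
    """Areas of a fixed model's segmentations across one eye's visits.

    All records must belong to a single (subject, eye); output has one row
    per visit, sorted by visit index, with the automated area in mm^2.
    """
    from . import io as gio  # deferred: io pulls PIL

    keys = {(r.subject_id, r.eye) for r in records}
    if len(keys) != 1:
        raise IntegrityError(f"longitudinal report needs one subject-eye, got {keys}")
    profile = profile or get_profile(records[0].device)
    rows = []
    for r in sorted(records, key=lambda r: r.visit_index):
        vol = gio.read_volume(r.volume_path, profile.native_spacing_mm,
                              record_id=r.record_id)
        pred = model.predict(vol)
        rows.append({"visit_index": r.visit_index, "area_auto_mm2": area_mm2(pred)})
    return pd.DataFrame(rows)


def coalescence_diagnostic(auto: EnFaceMask, manual: EnFaceMask) -> tuple[int, int]:
    """Connected-component counts (8-connectivity) of each mask.

    Fewer components in the automated mask than the manual one indicates the
    model merges neighbouring foci of multifocal GA.
    """
    ga, gm = np.asarray(auto.grid) > 0, np.asarray(manual.grid) > 0
    if ga.shape != gm.shape:
        raise ShapeError("mask shape mismatch")
    s = np.ones((3, 3), int)
    _, n_auto = ndimage.label(ga, structure=s)
    _, n_manual = ndimage.label(gm, structure=s)
    return int(n_auto), int(n_manual)
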