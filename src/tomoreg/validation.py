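"""Registration-accuracy assessment.

Implements the full validation suite used to judge kVCT/MVCT registration:

* global correlation coefficient (CC) over a border-trimmed overlap;
* landmark target registration error (TRE) in mm;
* slice-wise region-growing lung segmentation in the [-1000, -500] HU
  window, with left/right splitting;
* lung correspondence indices: percent volume error V_E, centroid distance
  C_E (mm) and Jaccard overlap, restricted to the axial sub-region imaged in
  both scans;
* exact Wilcoxon signed-rank comparison of rigid vs elastic indices and
  cohort aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError, GeometryError, UsageError
from .image import ImageVolume, Mask, extract_body_mask
from .transforms import transform_point

# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Labeled physical points (mm) in either the kVCT or MVCT frame."""

    entries: dict
    frame: str = "kVCT"

    def __post_init__(self):
        self.entries = {str(k): np.asarray(v, dtype=float)
                        for k, v in dict(self.entries).items()}

    def labels(self):
        return list(self.entries)

    def points(self, labels=None) -> np.ndarray:
        labels = labels if labels is not None else self.labels()
        return np.array([self.entries[l] for l in labels])

    def subset(self, labels) -> "LandmarkSet":
        return LandmarkSet({l: self.entries[l] for l in labels}, frame=self.frame)

    @classmethod
    def read_csv(cls, path, frame="kVCT") -> "LandmarkSet":
        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        need = {"label", "x_mm", "y_mm", "z_mm"}
        if not need.issubset(cols):
            raise UsageError(f"landmark file must have columns {sorted(need)}")
        return cls({str(r["label"]): (r["x_mm"], r["y_mm"], r["z_mm"])
                    for _, r in df.iterrows()}, frame=frame)

    def write_csv(self, path) -> None:
        rows = [{"label": l, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
                for l, p in self.entries.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def transform_landmarks(marks: LandmarkSet, transform,
                        exclusions: list | None = None) -> LandmarkSet:
    """Map every landmark through the registration transform.

    Landmarks outside the transform's domain are recorded in ``exclusions``
    (label + reason) rather than silently dropped.
    """
    out = {}
    for label, p in marks.entries.items():
        try:
            out[label] = transform_point(transform, p)
        except Exception as exc:  # DomainError in practice
            if exclusions is None:
                raise
            exclusions.append({"label": label, "reason": str(exc)})
    return LandmarkSet(out, frame="MVCT")


def target_registration_error(transformed: LandmarkSet,
                              reference: LandmarkSet):
    """Per-landmark Euclidean residual (mm) and (mean, sample SD, max).

    Returns (per_label: dict, summary: dict).  Only labels present in both
    sets are compared.
    """
    common = [l for l in transformed.labels() if l in reference.entries]
    if not common:
        raise UsageError("no common landmark labels between the two sets")
    residual = {l: float(np.linalg.norm(transformed.entries[l]
                                        - reference.entries[l]))
                for l in common}
    values = np.array(list(residual.values()))
    summary = {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "max": float(values.max()),
        "n": int(len(values)),
    }
    return residual, summary


# ---------------------------------------------------------------------------
# Correlation coefficient
# ---------------------------------------------------------------------------

def correlation_coefficient(fixed: ImageVolume, registered: ImageVolume,
                            border_xy: int = 30, border_z: int = 2) -> float:
    """Pearson correlation of intensities over the border-trimmed overlap.

    A band of ``border_xy`` voxels is stripped from each x/y side and
    ``border_z`` slices from each z end, removing areas interpolated from
    outside the image volume.
    """
    if fixed.shape != registered.shape:
        raise GeometryError("fixed and registered images must share geometry")
    bx, bz = border_xy, border_z
    nx, ny, nz = fixed.shape
    if nx <= 2 * bx or ny <= 2 * bx or nz <= 2 * bz:
        raise DegenerateInputError("border removal leaves no interior region")
    sl = (slice(bx, nx - bx), slice(bx, ny - bx), slice(bz, nz - bz))
    x = fixed.voxels[sl].ravel().astype(float)
    y = registered.voxels[sl].ravel().astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant interior region; CC undefined")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Lung segmentation
# ---------------------------------------------------------------------------

def segment_lungs_region_growing(img: ImageVolume, low: float = -1000.0,
                                 high: float = -500.0,
                                 body: Mask | None = None) -> Mask:
    """Slice-by-slice region growing of lung parenchyma in [low, high] HU.

    Per axial slice, every voxel in the intensity window that is not
    reachable from the exterior air at the slice border seeds a 2D grown
    region; grown contours are filled so enclosed vessels belong to the
    lung, and the slices are piled up into a binary volume.
    """
    if body is None:
        body = extract_body_mask(img)
    # half-HU guard: interpolated background fill must stay inside the window
    window = (img.voxels >= low - 0.5) & (img.voxels <= high)
    out = np.zeros(img.shape, dtype=bool)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for k in range(img.shape[2]):
        w = window[:, :, k]
        if not w.any():
            continue
        labels, n = ndimage.label(w, structure=structure)
        if n == 0:
            continue
        border = np.zeros_like(w)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        exterior = np.unique(labels[border & w])
        keep = np.ones(n + 1, dtype=bool)
        keep[0] = False
        keep[exterior] = False
        grown = keep[labels] & body.voxels[:, :, k]
        if grown.any():
            out[:, :, k] = ndimage.binary_fill_holes(grown)
    if not out.any():
        raise DegenerateInputError("no lung-range voxels found inside the body")
    return Mask.like(img, out)


@dataclass
class LungMask:
    """One lung's binary volume, tagged by side and originating image."""

    side: str
    mask: Mask
    source: str = "kVCT"


def split_left_right(lungs: Mask, body: Mask | None = None):
    """Separate a lung mask into (left, right) by 3D connectivity.

    The two largest components are assigned by centroid x (patient left =
    larger x in the assumed patient orientation).  A single merged component
    is split at the mid-sagittal plane of the body (or lung) mask.
    """
    if not lungs.voxels.any():
        raise DegenerateInputError("empty lung mask")
    labels, n = ndimage.label(lungs.voxels)
    sizes = ndimage.sum_labels(np.ones(lungs.shape), labels,
                               index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if n >= 2 and sizes[order[1]] >= 0.05 * sizes[order[0]]:
        a = labels == order[0] + 1
        b = labels == order[1] + 1
        ca = ndimage.center_of_mass(a)[0]
        cb = ndimage.center_of_mass(b)[0]
        left_vox, right_vox = (a, b) if ca >= cb else (b, a)
    else:
        # merged lungs (severe pathology): split by the mid-sagittal plane
        main = labels == order[0] + 1
        ref = body.voxels if body is not None else main
        mid = ndimage.center_of_mass(ref)[0]
        ix = np.arange(lungs.shape[0])[:, None, None]
        left_vox = main & (ix >= mid)
        right_vox = main & (ix < mid)
    left = LungMask(side="left", mask=Mask(left_vox, lungs.spacing, lungs.origin))
    right = LungMask(side="right", mask=Mask(right_vox, lungs.spacing, lungs.origin))
    return left, right


def restrict_to_common_extent(a: LungMask, b: LungMask, fov_z) -> tuple:
    """Zero both masks outside the common imaged z-interval [z0, z1] (mm)."""
    z0, z1 = float(fov_z[0]), float(fov_z[1])
    if z1 <= z0:
        raise DegenerateInputError("empty common z-extent")
    out = []
    for lm in (a, b):
        centers = lm.mask.origin[2] + np.arange(lm.mask.shape[2]) * lm.mask.spacing[2]
        inside = (centers >= z0) & (centers < z1)
        if not inside.any():
            raise DegenerateInputError("mask has no slices in the common extent")
        vox = lm.mask.voxels.copy()
        vox[:, :, ~inside] = False
        out.append(LungMask(side=lm.side,
                            mask=Mask(vox, lm.mask.spacing, lm.mask.origin),
                            source=lm.source))
    return tuple(out)


# ---------------------------------------------------------------------------
# Correspondence indices
# ---------------------------------------------------------------------------

def lung_volume(m: LungMask | Mask) -> float:
    """Binary volume in mm^3 (voxel count times voxel volume)."""
    mask = m.mask if isinstance(m, LungMask) else m
    return mask.count() * mask.voxel_volume


def volume_error(v_ct: float, v_reg: float) -> float:
    """Percent volume error V_E = 100 (V_CT - V_reg) / V_CT."""
    if v_ct <= 0:
        raise UsageError("reference volume must be positive")
    return 100.0 * (v_ct - v_reg) / v_ct


def _centroid_mm(mask: Mask) -> np.ndarray:
    if not mask.voxels.any():
        raise DegenerateInputError("empty mask has no centroid")
    com = np.asarray(ndimage.center_of_mass(mask.voxels))
    return mask.origin + com * mask.spacing


def centroid_error(a: LungMask | Mask, b: LungMask | Mask) -> float:
    """Euclidean distance (mm) between the binary centroids of two masks."""
    ma = a.mask if isinstance(a, LungMask) else a
    mb = b.mask if isinstance(b, LungMask) else b
    return float(np.linalg.norm(_centroid_mm(ma) - _centroid_mm(mb)))


def jaccard_index(a: LungMask | Mask, b: LungMask | Mask) -> float:
    """|A n B| / |A u B| of two same-geometry binary masks."""
    ma = a.mask if isinstance(a, LungMask) else a
    mb = b.mask if isinstance(b, LungMask) else b
    if ma.shape != mb.shape:
        raise GeometryError("masks must share geometry")
    union = int(np.logical_or(ma.voxels, mb.voxels).sum())
    if union == 0:
        raise DegenerateInputError("both masks empty; Jaccard undefined")
    inter = int(np.logical_and(ma.voxels, mb.voxels).sum())
    return inter / union


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(rigid_values, elastic_values) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's rule) and ties get average
    ranks.  For n <= 25 retained pairs the exact null distribution of W+ is
    built by dynamic programming over all 2^n sign assignments (exact also
    under ties); larger n uses the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(rigid_values, dtype=float)
    y = np.asarray(elastic_values, dtype=float)
    if x.shape != y.shape:
        raise UsageError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = _average_ranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    if n <= 25:
        # DP over doubled ranks so average ranks become integers
        r2 = np.rint(2 * ranks).astype(int)
        max_sum = int(r2.sum())
        counts = np.zeros(max_sum + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:max_sum + 1 - r]
            counts = counts + shifted
        counts /= counts.sum()
        w2 = int(np.rint(2 * w_pos))
        p_le = counts[:w2 + 1].sum()
        p_ge = counts[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = total / 2.0
    var = (ranks ** 2).sum() / 4.0
    z = (abs(w_pos - mean) - 0.5) / np.sqrt(var)
    from scipy.stats import norm
    return float(min(1.0, 2.0 * norm.sf(z)))


def _average_ranks(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(values)


# ---------------------------------------------------------------------------
# Session metrics and cohort aggregation
# ---------------------------------------------------------------------------

@dataclass
class LungIndices:
    """V_E (%), C_E (mm) and Jaccard for one lung at one stage."""

    volume_error_percent: float
    centroid_error_mm: float
    jaccard: float


@dataclass
class SessionMetrics:
    """All indices for one kVCT/MVCT registration session."""

    patient: str = ""
    session: str = ""
    cc: dict = field(default_factory=dict)            # stage -> CC
    tre: dict = field(default_factory=dict)           # stage -> summary dict
    tre_per_landmark: dict = field(default_factory=dict)
    lungs: dict = field(default_factory=dict)         # (stage, side) -> LungIndices

    def as_record(self) -> dict:
        rec = {"patient": self.patient, "session": self.session}
        for stage, value in self.cc.items():
            rec[f"cc_{stage}"] = value
        for stage, summ in self.tre.items():
            rec[f"tre_mean_{stage}"] = summ["mean"]
            rec[f"tre_sd_{stage}"] = summ["sd"]
            rec[f"tre_max_{stage}"] = summ["max"]
        for (stage, side), li in self.lungs.items():
            rec[f"ve_{side}_{stage}"] = li.volume_error_percent
            rec[f"ce_{side}_{stage}"] = li.centroid_error_mm
            rec[f"jac_{side}_{stage}"] = li.jaccard
        return rec


@dataclass
class CohortTable:
    """Per-session rows plus cohort aggregates and rigid-vs-elastic p-values."""

    rows: pd.DataFrame
    aggregates: dict
    wilcoxon_p: dict

    def to_json_dict(self) -> dict:
        return {
            "rows": self.rows.to_dict(orient="records"),
            "aggregates": self.aggregates,
            "wilcoxon_p": self.wilcoxon_p,
        }


def _mean_sd(values) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    return {"mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size)}


def aggregate_cohort(rows) -> CohortTable:
    """Cohort aggregation of session metrics.

    Produces per-patient TRE mean/SD/max (means of session means, as in the
    session-table convention), overall CC mean +- SD per stage, and cohort
    means of |V_E| and C_E pooled over both lungs and all sessions.  The
    Wilcoxon comparisons pair rigid against elastic values of the same
    quantity across sessions (and lungs, for the lung indices).
    """
    if not rows:
        raise UsageError("aggregate_cohort requires at least one session")
    if isinstance(rows[0], SessionMetrics):
        records = [r.as_record() for r in rows]
    else:
        records = list(rows)
    df = pd.DataFrame(records)
    agg: dict = {}
    for stage in ("rigid", "elastic"):
        if f"cc_{stage}" in df:
            agg[f"cc_{stage}"] = _mean_sd(df[f"cc_{stage}"])
        if f"tre_mean_{stage}" in df:
            per_patient = {}
            for patient, grp in df.groupby("patient"):
                per_patient[str(patient)] = {
                    "mean": float(grp[f"tre_mean_{stage}"].mean()),
                    "sd": float(grp[f"tre_mean_{stage}"].std(ddof=1))
                    if len(grp) > 1 else 0.0,
                    "max": float(grp[f"tre_max_{stage}"].max()),
                }
            agg[f"tre_{stage}_per_patient"] = per_patient
            agg[f"tre_{stage}"] = _mean_sd(df[f"tre_mean_{stage}"])
        ve_cols = [c for c in df.columns if c.startswith("ve_") and c.endswith(stage)]
        ce_cols = [c for c in df.columns if c.startswith("ce_") and c.endswith(stage)]
        jac_cols = [c for c in df.columns if c.startswith("jac_") and c.endswith(stage)]
        if ve_cols:
            pooled = np.abs(df[ve_cols].to_numpy(dtype=float).ravel())
            agg[f"abs_ve_{stage}"] = _mean_sd(pooled)
        if ce_cols:
            pooled = df[ce_cols].to_numpy(dtype=float).ravel()
            agg[f"ce_{stage}"] = _mean_sd(pooled)
        if jac_cols:
            pooled = df[jac_cols].to_numpy(dtype=float).ravel()
            agg[f"jac_{stage}"] = _mean_sd(pooled)
    wilcoxon = {}
    pairs = [("cc", "cc_rigid", "cc_elastic", False),
             ("tre_mean", "tre_mean_rigid", "tre_mean_elastic", False),
             ("tre_max", "tre_max_rigid", "tre_max_elastic", False)]
    for name, rc, ec, _ in pairs:
        if rc in df and ec in df and len(df) >= 5:
            try:
                wilcoxon[name] = wilcoxon_signed_rank(df[rc], df[ec])
            except DegenerateInputError:
                pass
    for name, prefix in (("abs_ve", "ve_"), ("ce", "ce_"), ("jac", "jac_")):
        r_cols = [c for c in df.columns if c.startswith(prefix) and c.endswith("rigid")]
        e_cols = [c.replace("rigid", "elastic") for c in r_cols]
        if r_cols and all(c in df for c in e_cols):
            r = df[r_cols].to_numpy(dtype=float).ravel()
            e = df[e_cols].to_numpy(dtype=float).ravel()
            ok = ~(np.isnan(r) | np.isnan(e))
            if ok.sum() >= 5:
                if name == "abs_ve":
                    r, e = np.abs(r[ok]), np.abs(e[ok])
                else:
                    r, e = r[ok], e[ok]
                try:
                    wilcoxon[name] = wilcoxon_signed_rank(r, e)
                except DegenerateInputError:
                    pass
    return CohortTable(rows=df, aggregates=agg, wilcoxon_p=wilcoxon)
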