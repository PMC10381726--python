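"""Synthetic chest-radiograph generator governed by cardiothoracic ratio.

Produces balanced two-class sets of grayscale thorax-like images in which
the class is a deterministic function of the cardiothoracic ratio (CTR):
controls draw CTR uniformly from [0.35, 0.45] and cardiomegaly cases from
[0.55, 0.70], mirroring the curation thresholds used for the real data
(control CTR <= 0.45, cardiomegaly CTR >= 0.55). Each record carries the
ground-truth heart and thorax masks, so the measured CTR (maximal cardiac
width over maximal inner thoracic width) can be checked against the drawn
value, and an optional basal-opacity confounder placed independently of
class.

The geometry is deliberately schematic — nested ellipses with Gaussian
noise and seeded placement jitter — not a photorealistic radiograph. What
it preserves is the decision-relevant structure: a bright cardiac
silhouette whose transverse width, relative to the thoracic cage, encodes
the label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticRecord",
    "generate_cxr",
    "generate_dataset",
    "measure_ctr",
    "requalify_labels",
]

MANIFEST_COLUMNS = [
    "Path",
    "PatientID",
    "Sex",
    "Age",
    "Frontal/Lateral",
    "AP/PA",
    "StudyOrder",
    "Cardiomegaly",
    "CTR",
]

# Table-style class summaries used to fill demographic columns: age ~
# N(54.4, 17.2) for controls vs N(62.9, 17.1) for cardiomegaly (truncated
# to [18, 100]); male fraction 65% vs 59%.
_AGE_PARAMS = {0: (54.4, 17.2), 1: (62.9, 17.1)}
_MALE_FRACTION = {0: 0.65, 1: 0.59}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the study conditions."""

    image_size: int = 320
    ctr_control: tuple[float, float] = (0.35, 0.45)
    ctr_cardiomegaly: tuple[float, float] = (0.55, 0.70)
    noise_sd: float = 0.03
    confounder_prob: float = 0.2
    jitter: float = 0.01  # placement jitter as a fraction of image size
    hard_mode: bool = False  # narrow the CTR gap for stress testing
    seed: int = 0

    def class_ctr_range(self, label: int) -> tuple[float, float]:
        if self.hard_mode:
            return (0.38, 0.49) if label == 0 else (0.51, 0.62)
        return self.ctr_control if label == 0 else self.ctr_cardiomegaly


@dataclass(frozen=True)
class SyntheticRecord:
    image: np.ndarray
    label: int
    ctr_true: float
    heart_mask: np.ndarray
    thorax_mask: np.ndarray
    patient_id: str
    view: str = "PA"
    study_order: int = 1
    sex: str = "Male"
    age: float = 60.0
    has_confounder: bool = False


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    y, x = np.mgrid[0:size, 0:size]
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def generate_cxr(
    ctr: float, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticRecord:
    """Draw one synthetic PA radiograph with the requested CTR.

    The thoracic cage is a bright ellipse containing two darker lung
    fields; the heart is a brighter low-central ellipse whose transverse
    width equals ``ctr`` times the inner thoracic width (heart aspect ratio
    fixed, so the mask area scales with ctr**2). Masks record the drawn
    shapes; the heart mask is clipped to the thorax so heart ⊂ thorax holds
    by construction. Deterministic given the generator state.
    """
    if not 0.2 <= ctr <= 0.9:
        raise ValueError("ctr must lie in [0.2, 0.9]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s = config.image_size
    jit = lambda: rng.uniform(-config.jitter, config.jitter) * s

    # thorax: inner cavity ellipse
    tcx, tcy = s / 2 + jit(), s * 0.52 + jit()
    ta, tb = s * 0.42, s * 0.38
    thorax = _ellipse_mask(s, tcx, tcy, ta, tb)

    # lungs: darker fields inside the thorax
    la, lb = ta * 0.42, tb * 0.80
    lung_l = _ellipse_mask(s, tcx - ta * 0.52, tcy, la, lb)
    lung_r = _ellipse_mask(s, tcx + ta * 0.52, tcy, la, lb)

    # heart: low-central, slightly toward the patient's left (image right);
    # transverse semi-axis = ctr * ta so width/inner-width = ctr exactly
    ha = ctr * ta
    hb = 0.95 * ha
    hcx, hcy = tcx + s * 0.02 + jit(), tcy + s * 0.08 + jit()
    heart = _ellipse_mask(s, hcx, hcy, ha, hb) & thorax

    img = np.full((s, s), 0.05)
    img[thorax] = 0.55
    img[lung_l | lung_r] = 0.25
    img[heart] = 0.85

    has_conf = bool(rng.uniform() < config.confounder_prob)
    if has_conf:
        # effusion-like basal opacity in one lung base, independent of class
        side = -1.0 if rng.uniform() < 0.5 else 1.0
        conf = _ellipse_mask(
            s, tcx + side * ta * 0.55, tcy + tb * 0.55, la * 0.9, lb * 0.35
        ) & (lung_l | lung_r) & ~heart
        img[conf] = 0.65

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, (s, s))
    img = np.clip(img, 0.0, 1.0)
    return SyntheticRecord(
        image=img,
        label=int(ctr >= 0.5),
        ctr_true=float(ctr),
        heart_mask=heart,
        thorax_mask=thorax,
        patient_id="synthetic",
        has_confounder=has_conf,
    )


def measure_ctr(heart_mask: np.ndarray, thorax_mask: np.ndarray) -> float:
    """Cardiothoracic ratio from masks: maximal horizontal cardiac extent
    over maximal horizontal inner thoracic extent."""

    def width(mask: np.ndarray) -> int:
        cols = np.where(mask.any(axis=0))[0]
        if cols.size == 0:
            raise ValueError("empty mask")
        return int(cols[-1] - cols[0] + 1)

    if not np.all(thorax_mask[heart_mask]):
        raise ValueError("heart mask must lie inside the thorax mask")
    return width(heart_mask) / width(thorax_mask)


def generate_dataset(
    n_per_class: int, config: SyntheticConfig
) -> tuple[list[SyntheticRecord], pd.DataFrame]:
    """Balanced dataset of ``2 * n_per_class`` records, one per synthetic
    patient, with a CheXpert-style manifest (string-typed label columns)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    records: list[SyntheticRecord] = []
    rows = []
    idx = 0
    for label in (0, 1):
        lo, hi = config.class_ctr_range(label)
        for _ in range(n_per_class):
            ctr = float(rng.uniform(lo, hi))
            rec = generate_cxr(ctr, config, rng)
            mean, sd = _AGE_PARAMS[label]
            age = float(np.clip(rng.normal(mean, sd), 18.0, 100.0))
            sex = "Male" if rng.uniform() < _MALE_FRACTION[label] else "Female"
            pid = f"patient{idx:05d}"
            rec = replace(
                rec,
                label=label,
                patient_id=pid,
                sex=sex,
                age=age,
            )
            records.append(rec)
            rows.append(
                {
                    "Path": f"{pid}_study1_view1.png",
                    "PatientID": pid,
                    "Sex": sex,
                    "Age": round(age, 1),
                    "Frontal/Lateral": "Frontal",
                    "AP/PA": "PA",
                    "StudyOrder": 1,
                    "Cardiomegaly": str(label),
                    "CTR": ctr,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return records, manifest


def requalify_labels(
    manifest: pd.DataFrame, label_column: str = "Cardiomegaly"
) -> pd.DataFrame:
    """Flip labels inconsistent with the measured CTR thresholds.

    A positive label with CTR <= 0.45 becomes control; a negative label
    with CTR >= 0.55 becomes cardiomegaly; intermediate ("doubtful") CTRs
    leave labels intact. Rows without a CTR value are skipped with a
    warning. Idempotent.
    """
    if "CTR" not in manifest.columns:
        raise ValueError("manifest has no CTR column")
    out = manifest.copy()
    ctr = pd.to_numeric(out["CTR"], errors="coerce")
    missing = ctr.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} rows without CTR skipped during requalification",
            stacklevel=2,
        )
    label = pd.to_numeric(out[label_column], errors="coerce")
    to_control = (label == 1) & (ctr <= 0.45) & ~missing
    to_disease = (label == 0) & (ctr >= 0.55) & ~missing
    was_str = out[label_column].dtype == object
    out.loc[to_control, label_column] = "0" if was_str else 0
    out.loc[to_disease, label_column] = "1" if was_str else 1
    return out
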