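"""Registration quality metrics: Dice overlap, endpoint error, residual maps.

The Dice similarity coefficient DSC(A, B) = 2|A∩B| / (|A| + |B|) measures
overlap between a region of the template (fixed) image and the corresponding
region of the registered image.  Per-region values are aggregated by an
unweighted mean over regions for which the coefficient is defined; a region
absent from both maps yields NaN ("undefined") and is excluded.
"""

from __future__ import annotations

import numpy as np

from .core import DeformationField, LabelMap, ScalarImage

__all__ = ["dice", "multi_label_dice", "endpoint_error", "residual_map"]


def dice(a, b) -> float:
    """Dice coefficient of two binary masks; NaN when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / denom


def multi_label_dice(template_labels, registered_labels):
    """Per-label Dice between two label maps plus the mean over defined values.

    Returns ``(table, mean)`` where ``table`` maps label ID -> Dice for every
    nonzero label present in either map.
    """
    ta = template_labels.labels if isinstance(template_labels, LabelMap) else np.asarray(template_labels)
    rb = registered_labels.labels if isinstance(registered_labels, LabelMap) else np.asarray(registered_labels)
    if ta.shape != rb.shape:
        raise ValueError(f"label map shapes differ: {ta.shape} vs {rb.shape}")
    ids = sorted(set(np.unique(ta)) | set(np.unique(rb)))
    table = {int(i): dice(ta == i, rb == i) for i in ids if i != 0}
    defined = [v for v in table.values() if not np.isnan(v)]
    mean = float(np.mean(defined)) if defined else float("nan")
    return table, mean


def endpoint_error(estimated, truth):
    """Mean and max per-voxel Euclidean displacement error, in voxels."""
    ea = estimated.displacements if isinstance(estimated, DeformationField) else np.asarray(estimated, float)
    tr = truth.displacements if isinstance(truth, DeformationField) else np.asarray(truth, float)
    if ea.shape != tr.shape:
        raise ValueError(f"field shapes differ: {ea.shape} vs {tr.shape}")
    norm = np.sqrt(((ea - tr) ** 2).sum(axis=0))
    return float(norm.mean()), float(norm.max())


def residual_map(fixed, image):
    """Signed difference ``image - fixed`` and its mean absolute value."""
    fa = fixed.values if isinstance(fixed, ScalarImage) else np.asarray(fixed, float)
    ia = image.values if isinstance(image, ScalarImage) else np.asarray(image, float)
    if fa.shape != ia.shape:
        raise ValueError(f"image shapes differ: {fa.shape} vs {ia.shape}")
    diff = ia - fa
    spacing = fixed.spacing if isinstance(fixed, ScalarImage) else None
    return ScalarImage(diff, spacing=spacing), float(np.abs(diff).mean())
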