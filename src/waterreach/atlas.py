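"""Cortical atlas ROI map and landmark-based registration.

The dorsal-cortex field of view is partitioned into 12 named regions per
hemisphere (motor, somatosensory subfields, visual and retrosplenial
areas).  Right-hemisphere regions are contralateral to the reaching (left)
paw.  Registration maps the packaged reference atlas into a session's
image frame with a least-squares affine fitted on user-supplied named
landmarks (bregma, lambda, lateral anchors); the label image is warped by
nearest neighbor so labels stay integral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .errors import RegistrationError

ROI_BASENAMES = (
    "M1",
    "M2",
    "sspm",
    "sspfl",
    "ssphl",
    "sspun",
    "sspn",
    "sspbfd",
    "ssptr",
    "visp",
    "rspagl",
    "rspd",
)
HEMISPHERES = ("contra", "ipsi")  # contra = right hemisphere (left paw task)

# Approximate anatomical seed positions, (row offset from anterior pole
# fraction, column offset from midline fraction); mirrored across midline.
_SEEDS = {
    "M2": (0.28, 0.10),
    "M1": (0.34, 0.30),
    "sspfl": (0.46, 0.34),
    "sspm": (0.50, 0.52),
    "sspn": (0.40, 0.48),
    "ssphl": (0.56, 0.30),
    "sspun": (0.58, 0.44),
    "sspbfd": (0.54, 0.60),
    "ssptr": (0.66, 0.34),
    "visp": (0.80, 0.44),
    "rspagl": (0.78, 0.20),
    "rspd": (0.76, 0.08),
}


@dataclass
class AtlasROIMap:
    """Integer label image with named ROIs and named landmark points.

    ``names`` maps "<roi>_<hemisphere>" to its integer label; ``landmarks``
    are (x, y) points in the map's own coordinate frame.  After
    registration, ``affine`` holds the 2x3 reference-to-image transform and
    ``residual_px`` the RMS landmark misfit.
    """

    label_image: np.ndarray
    names: dict[str, int]
    landmarks: dict[str, tuple[float, float]]
    affine: np.ndarray | None = None
    residual_px: float = 0.0
    pixel_size_um: float = 68.0
    _centroids: dict = field(default_factory=dict, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape

    def mask(self, roi: str) -> np.ndarray:
        if roi not in self.names:
            raise KeyError(f"unknown ROI {roi!r}")
        return self.label_image == self.names[roi]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_image > 0

    def centroid(self, roi: str) -> tuple[float, float]:
        """ROI mask centroid as (row, col)."""
        if roi not in self._centroids:
            rows, cols = np.nonzero(self.mask(roi))
            if rows.size == 0:
                raise RegistrationError(f"ROI {roi!r} is empty")
            self._centroids[roi] = (float(rows.mean()), float(cols.mean()))
        return self._centroids[roi]

    def save(self, label_path, meta_path) -> None:
        """Write the label image as PNG and names/landmarks as JSON."""
        from imageio.v3 import imwrite

        imwrite(label_path, self.label_image.astype(np.uint8))
        meta = {
            "names": self.names,
            "landmarks": {k: list(v) for k, v in self.landmarks.items()},
            "pixel_size_um": self.pixel_size_um,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, label_path, meta_path) -> "AtlasROIMap":
        from imageio.v3 import imread

        label = imread(label_path).astype(np.int32)
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(
            label_image=label,
            names={k: int(v) for k, v in meta["names"].items()},
            landmarks={k: tuple(v) for k, v in meta["landmarks"].items()},
            pixel_size_um=float(meta.get("pixel_size_um", 68.0)),
        )


def default_atlas(shape: tuple[int, int] = (128, 128)) -> AtlasROIMap:
    """Reference atlas built procedurally (synthetic stand-in geometry).

    A plausible dorsal-cortex layout, not a tracing of a real atlas: an
    elliptical brain mask split at the vertical midline, each hemisphere
    partitioned among 12 anatomically arranged seeds by nearest-seed
    assignment.  Landmarks: bregma and lambda on the midline plus two
    lateral anchors.
    """
    h, w = shape
    cr, cc = 0.46 * h, 0.5 * w
    rr, rc = 0.36 * h, 0.42 * w
    rows, cols = np.mgrid[0:h, 0:w]
    brain = ((rows - cr) / rr) ** 2 + ((cols - cc) / rc) ** 2 <= 1.0

    top = cr - rr  # anterior pole row
    names: dict[str, int] = {}
    seeds = []
    label = 0
    for hemi, sign in (("contra", +1), ("ipsi", -1)):  # contra = right
        for roi in ROI_BASENAMES:
            fr, fc = _SEEDS[roi]
            label += 1
            names[f"{roi}_{hemi}"] = label
            seeds.append((top + fr * 2 * rr, cc + sign * fc * 0.5 * w, label))

    label_image = np.zeros(shape, np.int32)
    seed_arr = np.array([(r, c) for r, c, _ in seeds])
    seed_lab = np.array([lab for _, _, lab in seeds])
    right = cols >= cc
    for hemi_mask, hemi_sel in (
        (brain & right, seed_arr[:, 1] >= cc),
        (brain & ~right, seed_arr[:, 1] < cc),
    ):
        pts = np.column_stack(np.nonzero(hemi_mask))
        if pts.size == 0:
            continue
        s = seed_arr[hemi_sel]
        labs = seed_lab[hemi_sel]
        d2 = ((pts[:, None, :] - s[None, :, :]) ** 2).sum(-1)
        label_image[hemi_mask] = labs[np.argmin(d2, axis=1)]

    landmarks = {
        "bregma": (cc, top + 0.10 * 2 * rr),
        "lambda": (cc, top + 0.92 * 2 * rr),
        "anchor_left": (cc - 0.8 * rc, cr),
        "anchor_right": (cc + 0.8 * rc, cr),
    }
    return AtlasROIMap(label_image=label_image, names=names, landmarks=landmarks)


def register_atlas(
    image_landmarks: dict[str, tuple[float, float]],
    reference: AtlasROIMap,
    output_shape: tuple[int, int] | None = None,
) -> AtlasROIMap:
    """Fit reference -> image affine on matched landmarks and warp labels.

    Landmarks are matched by name; at least three non-collinear pairs are
    required.  The label image is resampled by nearest neighbor into the
    session frame; the RMS residual of the fitted landmarks is reported.
    """
    common = [k for k in reference.landmarks if k in image_landmarks]
    if len(common) < 3:
        raise RegistrationError(
            f"need >= 3 matched landmarks, got {len(common)}: {common}"
        )
    ref_pts = np.array([reference.landmarks[k] for k in common], float)
    img_pts = np.array([image_landmarks[k] for k in common], float)

    centered = ref_pts - ref_pts.mean(0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
        raise RegistrationError("landmarks are collinear")

    if hasattr(sktransform.AffineTransform, "from_estimate"):
        tf = sktransform.AffineTransform.from_estimate(ref_pts, img_pts)
        if not tf:  # maps reference -> image
            raise RegistrationError("affine estimation failed")
    else:  # scikit-image < 0.26
        tf = sktransform.AffineTransform()
        if not tf.estimate(ref_pts, img_pts):
            raise RegistrationError("affine estimation failed")

    mapped = tf(ref_pts)
    residual = float(np.sqrt(np.mean(np.sum((mapped - img_pts) ** 2, axis=1))))

    shape = output_shape or reference.shape
    warped = sktransform.warp(
        reference.label_image.astype(float),
        inverse_map=tf.inverse,
        output_shape=shape,
        order=0,
        preserve_range=True,
        cval=0.0,
    ).astype(np.int32)

    for name in reference.names:
        if not np.any(warped == reference.names[name]):
            raise RegistrationError(f"ROI {name!r} empty after warping")

    return AtlasROIMap(
        label_image=warped,
        names=dict(reference.names),
        landmarks={k: tuple(tf(reference.landmarks[k])[0]) for k in reference.landmarks},
        affine=np.asarray(tf.params)[:2, :],
        residual_px=residual,
        pixel_size_um=reference.pixel_size_um,
    )
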