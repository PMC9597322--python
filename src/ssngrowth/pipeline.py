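"""End-to-end phantom pipeline: simulate -> align -> measure -> label.

Glues the stages together the way the longitudinal analysis runs on
real follow-up CT: each later exam is rigidly registered to the first,
lesions are segmented (fixture segmenter on phantoms), centroids are
paired across time, the matched nodule is measured at every time point
and the growth label is derived from the last consecutive pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import NoduleMask, VoxelGrid
from .labels import annualized_mass_rate, growth_label
from .measure import NoduleMeasurement, growth_record, measure
from .pairing import pair_nodules, register_rigid, segment_phantom
from .phantom import CohortSample

__all__ = ["PipelineResult", "run_phantom_pipeline", "build_model_dataset"]


def build_model_dataset(samples: list[CohortSample], voi_size: int = 32
                        ) -> dict[str, np.ndarray]:
    """Assemble (prior, current, target) arrays for model training.

    For a 3-exam trajectory the model input is the (T0, T1) VOI pair
    and the target is the annualized mass rate realised between T1 and
    T2; for a 2-exam trajectory the input is the T0 VOI alone (no
    prior) and the target is realised between T0 and T1.  VOIs are
    ``voi_size``^3 crops at 1 mm centred on the true nodule position.
    """
    from .pairing import extract_voi

    cur, pri, present, ys, labels = [], [], [], [], []
    for s in samples:
        n = len(s.exams)
        if n >= 3:
            g0, g1 = s.exams[0][0], s.exams[1][0]
            c0, c1 = s.exams[0][2].center, s.exams[1][2].center
            pri.append(extract_voi(g0, c0, voi_size).values)
            cur.append(extract_voi(g1, c1, voi_size).values)
            present.append(True)
        else:
            g0, c0 = s.exams[0][0], s.exams[0][2].center
            cur.append(extract_voi(g0, c0, voi_size).values)
            present.append(False)
        truth_last = s.exams[-1][2]
        ys.append(truth_last.annualized_mass_rate)
        labels.append(truth_last.growth_label)
    return {
        "current": np.asarray(cur, dtype=np.float32),
        "prior": np.asarray(pri, dtype=np.float32) if pri
        else np.empty((0,) + (voi_size,) * 3, np.float32),
        "prior_present": np.asarray(present, bool),
        "y": np.asarray(ys, float),
        "label": np.asarray(labels, bool),
    }


@dataclass
class PipelineResult:
    """Measured trajectory and derived growth label for one nodule."""

    subject_id: str
    measurements: list[NoduleMeasurement]
    y: float
    growth_label: bool
    matched: bool


def run_phantom_pipeline(sample: CohortSample, *, use_registration: bool = True,
                         segment_kw: dict | None = None) -> PipelineResult:
    """Run the measurement pipeline on one simulated trajectory.

    Segmentation thresholds at the HU midpoint between parenchyma and
    lesion (exact on noiseless phantoms); registration aligns each
    follow-up exam back to the baseline scan before centroid pairing.
    The label comes from the measured masses of the last exam pair and
    the true inter-exam interval.
    """
    spec = sample.spec
    grids = [g for g, _, _ in sample.exams]
    # threshold at the HU midpoint between parenchyma and the lesion's
    # (possibly drifted) attenuation at each exam
    seg_masks = []
    for (g, _, truth) in sample.exams:
        kw = dict(threshold=(spec.background_hu + truth.analytic_mean_hu) / 2.0)
        if segment_kw:
            kw.update(segment_kw)
        seg_masks.append(segment_phantom(g, **kw))
    centroids = [m.centroid_world() for m in seg_masks]

    matched = True
    for k in range(1, len(grids)):
        transform = None
        if use_registration:
            transform = register_rigid(grids[k], grids[0])
        match = pair_nodules([centroids[k]], [centroids[0]],
                             transform=transform)
        if not match.pairs:
            matched = False

    meas = [measure(g, m) for g, m in zip(grids, seg_masks)]
    dt = sample.interval_days[-1]
    y = annualized_mass_rate(meas[-2].mass, meas[-1].mass, dt)
    return PipelineResult(
        subject_id=sample.subject_id,
        measurements=meas,
        y=y,
        growth_label=growth_label(y),
        matched=matched,
    )
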