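"""The 1150-slot feature vector and its index codec.

Per subject and cost, the pipeline concatenates:

====================  =======  ==========================================
slots                 count    content
====================  =======  ==========================================
1-68                  68       cortical thickness (CT), DK regions 1-68
69-136                68       cortical volume (CV)
137-204               68       cortical surface area (CS)
205-272               68       thickness-network nodal degree (SCN ND)
273-340               68       thickness-network nodal path length (SCN NL)
341-610               270      functional full band: NL, ND, BC x 90 AAL
611-880               270      functional slow-4:    NL, ND, BC x 90 AAL
881-1150              270      functional slow-5:    NL, ND, BC x 90 AAL
====================  =======  ==========================================

so 204 raw morphometry + 136 structural-network + 810 functional-network
features.  ``decode_index`` / ``encode_descriptor`` form a bijection
between 1..1150 and feature descriptors.

The structural blocks follow the FreeSurfer aparc region order (left
hemisphere 1-34, right 35-68); functional blocks follow the canonical
AAL 1-90 numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlases import AAL90_LABELS, DK68_LABELS, N_AAL, N_DK
from .cohort import SubjectRecord
from .graphmetrics import nodal_metrics
from .networks import binarize_at_cost, functional_network, thickness_network

N_FEATURES = 1150
N_STRUCTURAL = 204
N_SCN = 136
N_FCN = 810

FCN_BANDS = ("full", "slow4", "slow5")
_FCN_METRICS = ("NL", "ND", "BC")
_FCN_START = 341  # first functional slot (1-based)


@dataclass(frozen=True)
class FeatureDescriptor:
    """What one slot of the 1150-vector measures."""

    index: int
    modality: str  # "structural" | "scn" | "fcn"
    measure: str   # CT | CV | CS | ND | NL | BC
    band: str      # "none" | "full" | "slow4" | "slow5"
    region_id: int  # 1-based atlas index
    region_label: str

    @property
    def name(self) -> str:
        if self.modality == "structural":
            return f"struct_{self.measure.lower()}_{self.region_label}"
        if self.modality == "scn":
            return f"scn_{self.measure.lower()}_{self.region_label}"
        return f"fcn_{self.band}_{self.measure.lower()}_{self.region_label}"


def decode_index(index: int) -> FeatureDescriptor:
    """Map a 1-based feature index to its descriptor."""
    if not 1 <= index <= N_FEATURES:
        raise ValueError(f"feature index must be in 1..{N_FEATURES}, got {index}")
    i = index - 1
    if i < N_STRUCTURAL:
        measure = ("CT", "CV", "CS")[i // N_DK]
        region = i % N_DK
        return FeatureDescriptor(
            index, "structural", measure, "none", region + 1, DK68_LABELS[region]
        )
    i -= N_STRUCTURAL
    if i < N_SCN:
        measure = ("ND", "NL")[i // N_DK]
        region = i % N_DK
        return FeatureDescriptor(index, "scn", measure, "none", region + 1, DK68_LABELS[region])
    i -= N_SCN
    band = FCN_BANDS[i // (3 * N_AAL)]
    i %= 3 * N_AAL
    measure = _FCN_METRICS[i // N_AAL]
    region = i % N_AAL
    return FeatureDescriptor(index, "fcn", measure, band, region + 1, AAL90_LABELS[region])


def encode_descriptor(
    modality: str, measure: str, region_id: int, band: str = "none"
) -> int:
    """Inverse of :func:`decode_index` (1-based ``region_id``)."""
    if modality == "structural":
        block = ("CT", "CV", "CS").index(measure)
        return block * N_DK + region_id
    if modality == "scn":
        block = ("ND", "NL").index(measure)
        return N_STRUCTURAL + block * N_DK + region_id
    if modality == "fcn":
        band_block = FCN_BANDS.index(band)
        metric_block = _FCN_METRICS.index(measure)
        return _FCN_START - 1 + band_block * 3 * N_AAL + metric_block * N_AAL + region_id
    raise ValueError(f"unknown modality {modality!r}")


def feature_names() -> list[str]:
    return [decode_index(i).name for i in range(1, N_FEATURES + 1)]


def assemble_features(
    subject: SubjectRecord,
    cost: float,
    alpha: float = 0.01,
    rank_mode: str = "signed",
    unreachable: str = "penalty",
) -> np.ndarray:
    """Assemble the 1150-vector for one subject at one network cost."""
    out = np.empty(N_FEATURES)
    out[0:68] = subject.thickness
    out[68:136] = subject.volume
    out[136:204] = subject.area

    scn = binarize_at_cost(thickness_network(subject.thickness, alpha=alpha), cost)
    scn_metrics = nodal_metrics(scn, unreachable=unreachable)
    out[204:272] = scn_metrics.nd
    out[272:340] = scn_metrics.nl

    pos = _FCN_START - 1
    for band in FCN_BANDS:
        if band not in subject.timeseries:
            raise ValueError(f"subject {subject.subject_id} is missing band {band!r}")
        fcn = binarize_at_cost(
            functional_network(subject.timeseries[band], band=band), cost, rank_mode=rank_mode
        )
        metrics = nodal_metrics(fcn, unreachable=unreachable)
        out[pos : pos + N_AAL] = metrics.nl
        out[pos + N_AAL : pos + 2 * N_AAL] = metrics.nd
        out[pos + 2 * N_AAL : pos + 3 * N_AAL] = metrics.bc
        pos += 3 * N_AAL
    return out


@dataclass
class FeatureMatrix:
    """N x 1150 design matrix for one two-group contrast at one cost."""

    values: np.ndarray
    groups: np.ndarray          # group label per row
    y: np.ndarray               # 1 = positive class, 0 = negative
    positive: str
    cost: float
    subject_ids: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=feature_names(), index=self.subject_ids)
        df.insert(0, "group", self.groups)
        return df


def build_design_matrix(
    cohort: Sequence[SubjectRecord],
    groups: tuple[str, str],
    cost: float,
    **assemble_kwargs,
) -> FeatureMatrix:
    """Stack feature vectors for the two requested groups.

    The second group of ``groups`` is the positive class (the later disease
    stage in both contrasts studied here: MCIc in MCInc-vs-MCIc, AD in
    MCIc-vs-AD).
    """
    selected = [s for s in cohort if s.group in groups]
    present = {s.group for s in selected}
    for g in groups:
        if g not in present:
            raise ValueError(f"group {g!r} absent from cohort")
    values = np.stack([assemble_features(s, cost, **assemble_kwargs) for s in selected])
    group_arr = np.array([s.group for s in selected])
    y = (group_arr == groups[1]).astype(int)
    return FeatureMatrix(
        values=values,
        groups=group_arr,
        y=y,
        positive=groups[1],
        cost=cost,
        subject_ids=[s.subject_id for s in selected],
    )
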