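"""Feature schemas, subject-by-feature tables and fatigue outcome labels.

The pipeline consumes three modalities of tabular features, one row per
subject:

``smri``
    Structural MRI morphometrics: 52 subcortical volumes plus 8 morphometric
    statistics for each of 68 cortical parcellations (34 per hemisphere),
    596 features in total.
``dti``
    Diffusion metrics: 4 tensor-derived measures (fractional anisotropy,
    mean / longitudinal / radial diffusivity) for each of 76 fiber tracts,
    304 features in total.
``clinical``
    A configurable list of clinical variables (default: age, sex, disease
    duration, weight, baseline fatigue score, pain VAS, HADS depression and
    anxiety).

Outcome labels derive from the Chalder Fatigue Scale (CFS) measured at
baseline and at 6 months: a subject is an *improver* when
``delta_cfs = baseline - followup >= threshold`` (default threshold 2;
lower CFS means less fatigue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("smri", "dti", "clinical")

#: Desikan-Killiany cortical parcellations (34 per hemisphere).
CORTICAL_PARCELLATIONS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: Eight morphometric statistics computed per cortical parcellation.
CORTICAL_STATISTICS: tuple[str, ...] = (
    "surface_area", "gray_matter_volume", "thickness_mean", "thickness_std",
    "mean_curvature", "gaussian_curvature", "folding_index",
    "curvature_index",
)

_LATERAL_STRUCTURES = (
    "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
    "Cerebellum-Cortex", "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC", "vessel",
    "choroid-plexus", "Cerebral-White-Matter", "Cerebral-Cortex",
    "WM-hypointensities", "non-WM-hypointensities", "Substancia-Nigra",
    "Cerebral-Exterior",
)
_MIDLINE_STRUCTURES = (
    "3rd-Ventricle", "4th-Ventricle", "5th-Ventricle", "Brain-Stem", "CSF",
    "Optic-Chiasm", "CC_Posterior", "CC_Mid_Posterior", "CC_Central",
    "CC_Mid_Anterior", "CC_Anterior", "WM-hypointensities-total",
)

#: 52 subcortical segmentation volumes (40 lateral + 12 midline).
SUBCORTICAL_STRUCTURES: tuple[str, ...] = tuple(
    f"{hemi}-{s}" for s in _LATERAL_STRUCTURES for hemi in ("Left", "Right")
) + _MIDLINE_STRUCTURES

N_TRACTS = 76

#: Tensor-derived diffusion measures per tract: fractional anisotropy,
#: mean, longitudinal and radial diffusivity.
DIFFUSION_MEASURES: tuple[str, ...] = ("fa", "md", "ld", "rd")

DEFAULT_CLINICAL_VARIABLES: tuple[str, ...] = (
    "age", "sex", "disease_duration", "weight", "cfs_baseline", "pain_vas",
    "hads_depression", "hads_anxiety",
)

#: Plausible Chalder Fatigue Scale score range (bimodal scoring, 11 items).
DEFAULT_CFS_BOUNDS = (0, 11)

SUBJECT_ID_COLUMN = "subject_id"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature set for one modality.

    ``group_tags`` mark features that belong together (the parcellation for
    cortical statistics, the tract for diffusion measures); the synthetic
    cohort generator correlates features sharing a tag, as real
    morphometrics do.
    """

    modality: str
    feature_names: tuple[str, ...]
    group_tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if len(self.feature_names) != len(self.group_tags):
            raise ValueError("feature_names and group_tags length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names in schema")

    def __len__(self) -> int:
        return len(self.feature_names)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def build_schema(
    modality: str, clinical_names: Sequence[str] | None = None
) -> FeatureSchema:
    """Construct the deterministic feature schema for one modality.

    ``smri`` yields 596 features (52 subcortical volumes, then 68
    parcellations x 8 statistics); ``dti`` yields 304 (76 tracts x 4
    measures); ``clinical`` uses ``clinical_names`` (default: the standard
    8-variable clinical set).
    """
    if modality == "smri":
        names = [f"{s}_volume" for s in SUBCORTICAL_STRUCTURES]
        tags = ["subcortical"] * len(names)
        for hemi in ("lh", "rh"):
            for parc in CORTICAL_PARCELLATIONS:
                for stat in CORTICAL_STATISTICS:
                    names.append(f"{hemi}_{parc}_{stat}")
                    tags.append(f"{hemi}_{parc}")
        return FeatureSchema("smri", tuple(names), tuple(tags))
    if modality == "dti":
        names, tags = [], []
        for t in range(1, N_TRACTS + 1):
            for measure in DIFFUSION_MEASURES:
                names.append(f"tract{t:02d}_{measure}")
                tags.append(f"tract{t:02d}")
        return FeatureSchema("dti", tuple(names), tuple(tags))
    if modality == "clinical":
        names = tuple(clinical_names) if clinical_names is not None \
            else DEFAULT_CLINICAL_VARIABLES
        if len(set(names)) != len(names):
            raise ValueError("duplicate clinical feature names")
        return FeatureSchema("clinical", tuple(names), tuple(names))
    raise ValueError(f"unknown modality {modality!r}")


@dataclass
class FeatureTable:
    """Subjects x features matrix bound to a :class:`FeatureSchema`."""

    schema: FeatureSchema
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.subject_ids), len(self.schema)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x "
                f"{len(self.schema)} features"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.feature_names))
        df.insert(0, SUBJECT_ID_COLUMN, self.subject_ids)
        return df


@dataclass
class OutcomeLabels:
    """Per-subject fatigue change and binary improver class.

    ``delta_cfs = cfs_baseline - cfs_followup``; ``improver`` is
    ``delta_cfs >= threshold``.
    """

    subject_ids: list[str]
    cfs_baseline: np.ndarray
    cfs_followup: np.ndarray
    threshold: int = 2
    delta_cfs: np.ndarray = field(init=False)
    improver: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cfs_baseline = np.asarray(self.cfs_baseline, dtype=int)
        self.cfs_followup = np.asarray(self.cfs_followup, dtype=int)
        n = len(self.subject_ids)
        if self.cfs_baseline.shape != (n,) or self.cfs_followup.shape != (n,):
            raise ValueError("score arrays must match the subject list")
        self.delta_cfs = self.cfs_baseline - self.cfs_followup
        self.improver = self.delta_cfs >= self.threshold

    @property
    def n_improvers(self) -> int:
        return int(self.improver.sum())

    @property
    def n_nonimprovers(self) -> int:
        return int((~self.improver).sum())

    def y_signed(self) -> np.ndarray:
        """Labels encoded +1 = improver (positive class), -1 = non-improver."""
        return np.where(self.improver, 1, -1)


def label_improvement(
    cfs_baseline: Sequence[int],
    cfs_followup: Sequence[int],
    threshold: int = 2,
    subject_ids: Sequence[str] | None = None,
    bounds: tuple[int, int] = DEFAULT_CFS_BOUNDS,
) -> OutcomeLabels:
    """Derive improver / non-improver labels from paired fatigue scores.

    A decrease of at least ``threshold`` points between baseline and
    follow-up marks clinically relevant improvement.
    """
    baseline = np.asarray(cfs_baseline, dtype=int)
    followup = np.asarray(cfs_followup, dtype=int)
    if baseline.shape != followup.shape or baseline.ndim != 1:
        raise ValueError("baseline and follow-up score lists must match")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    lo, hi = bounds
    for name, scores in (("baseline", baseline), ("follow-up", followup)):
        if ((scores < lo) | (scores > hi)).any():
            raise ValueError(f"{name} scores outside plausible range {bounds}")
    ids = list(subject_ids) if subject_ids is not None else [
        f"S{i + 1:03d}" for i in range(len(baseline))
    ]
    labels = OutcomeLabels(ids, baseline, followup, threshold=threshold)
    logger.info(
        "labelled %d improvers / %d non-improvers (threshold %d)",
        labels.n_improvers, labels.n_nonimprovers, threshold,
    )
    return labels


def _read_delimited(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype={SUBJECT_ID_COLUMN: str},
                       float_precision="round_trip")


def read_feature_table(
    path: str | Path,
    schema: FeatureSchema,
    sep: str = ",",
    drop_incomplete: bool = False,
) -> FeatureTable:
    """Read a delimited feature table and validate it against ``schema``.

    All schema columns must be present (missing columns are fatal); extra
    columns are ignored with a warning; column order is normalized to the
    schema order. Missing values are fatal unless ``drop_incomplete`` drops
    those subjects (logged).
    """
    df = _read_delimited(path, sep)
    if SUBJECT_ID_COLUMN not in df.columns:
        raise ValueError(f"missing required column {SUBJECT_ID_COLUMN!r}")
    missing = [n for n in schema.feature_names if n not in df.columns]
    if missing:
        raise ValueError(f"missing schema columns: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    extra = [c for c in df.columns
             if c != SUBJECT_ID_COLUMN and c not in schema.feature_names]
    if extra:
        logger.warning("ignoring %d non-schema columns: %s",
                       len(extra), extra[:5])
    sub = df[list(schema.feature_names)]
    try:
        values = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in feature table: {exc}") from exc
    ids = df[SUBJECT_ID_COLUMN].tolist()
    if drop_incomplete:
        keep = ~np.isnan(values).any(axis=1)
        if not keep.all():
            dropped = [i for i, k in zip(ids, keep) if not k]
            logger.warning("dropping %d incomplete subjects: %s",
                           len(dropped), dropped)
        values = values[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    return FeatureTable(schema, ids, values)


def write_feature_table(
    table: FeatureTable, path: str | Path, sep: str = ","
) -> None:
    """Write a feature table; values round-trip exactly through
    :func:`read_feature_table` (shortest-repr float serialization)."""
    if table.n_subjects == 0:
        raise ValueError("refusing to write a table with no subjects")
    # repr() emits the shortest digit string that round-trips the double
    # exactly; pandas' default float formatter does not
    table.to_dataframe().to_csv(path, sep=sep, index=False,
                                float_format=lambda x: repr(float(x)))


def read_outcome(
    path: str | Path, sep: str = ",", threshold: int = 2
) -> OutcomeLabels:
    """Read a per-subject fatigue score file (subject_id, cfs_baseline,
    cfs_followup) and derive outcome labels."""
    df = _read_delimited(path, sep)
    for col in (SUBJECT_ID_COLUMN, "cfs_baseline", "cfs_followup"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    return label_improvement(
        df["cfs_baseline"].to_numpy(),
        df["cfs_followup"].to_numpy(),
        threshold=threshold,
        subject_ids=df[SUBJECT_ID_COLUMN].tolist(),
    )


def write_outcome(labels: OutcomeLabels, path: str | Path,
                  sep: str = ",") -> None:
    pd.DataFrame({
        SUBJECT_ID_COLUMN: labels.subject_ids,
        "cfs_baseline": labels.cfs_baseline,
        "cfs_followup": labels.cfs_followup,
    }).to_csv(path, sep=sep, index=False)
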