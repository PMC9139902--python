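"""Radiomic feature catalogue, naming convention, and feature-table I/O.

The catalogue models the standard PyRadiomics extraction output for a
multi-sequence liver MRI protocol: 14 shape descriptors computed once per
VOI (all sequences share one segmentation), plus 18 first-order and 75
texture features for each of the four sequences (T2, arterial, portal and
tardive post-contrast phases), 14 + 4 x 93 = 386 features in total.

Feature names follow the field's ``<sequence> <group> <BaseName>`` pattern
(e.g. ``T2 gldm Dependence Non Uniformity Normalized``); both space- and
underscore-delimited dialects are accepted on input, while the canonical
on-disk form is underscore-joined with an upper-camel-case base name
(``T2_gldm_DependenceNonUniformityNormalized``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FeatureNameError, FeatureTableError, MissingValueError, PairingError

SEQUENCES = ("SHAPE-global", "T2", "ART", "PORT", "TARD")
GROUPS = ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")

#: per-sequence sequence tokens as they appear in feature names
_SEQ_TOKENS = {"T2": "T2", "ART": "ART", "PORT": "PORT", "TARD": "TARD", "SHAPE": "SHAPE-global"}

RESERVED_COLUMNS = ("subject_id", "tissue", "grade")

TISSUES = ("HCC", "HT")
GRADES = ("G1", "G2", "G3", "NA")

# PyRadiomics default feature classes; the texture total 24+16+16+14+5 = 75.
SHAPE_FEATURES = (
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
)
FIRSTORDER_FEATURES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median", "Minimum",
    "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
    "TotalEnergy", "Uniformity", "Variance",
)
GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
GLDM_FEATURES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

_GROUP_FEATURES: Mapping[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

# groups extracted per sequence, in catalogue order
_PER_SEQUENCE_GROUPS = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass(frozen=True, order=True)
class FeatureDescriptor:
    """Structured name of one radiomic feature.

    ``sequence`` is the acquisition the feature was computed on
    (``SHAPE-global`` for geometry features, which attach to the single
    shared VOI rather than to any sequence); ``group`` is the feature class;
    ``base_name`` is the IBSI-style upper-camel-case feature name.
    """

    sequence: str
    group: str
    base_name: str

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise FeatureNameError(f"unknown sequence {self.sequence!r}")
        if self.group not in GROUPS:
            raise FeatureNameError(f"unknown feature group {self.group!r}")
        if (self.group == "shape") != (self.sequence == "SHAPE-global"):
            raise FeatureNameError(
                "shape features must (and only they may) use the SHAPE-global sequence; "
                f"got sequence={self.sequence!r}, group={self.group!r}"
            )
        if not self.base_name:
            raise FeatureNameError("empty feature base name")

    @property
    def name(self) -> str:
        """Canonical underscore-joined name."""
        if self.sequence == "SHAPE-global":
            return f"SHAPE_{self.base_name}"
        return f"{self.sequence}_{self.group}_{self.base_name}"

    @property
    def display_name(self) -> str:
        """Space-separated human-readable name, base name split into words."""
        words = _split_camel(self.base_name)
        if self.sequence == "SHAPE-global":
            return " ".join(["SHAPE", *words])
        return " ".join([self.sequence, self.group, *words])


def _split_camel(base: str) -> list[str]:
    # split before an uppercase letter preceded by a lowercase letter, so
    # "LargeDependenceHighGrayLevelEmphasis" -> Large Dependence High Gray
    # Level Emphasis while "10Percentile", "MCC" and "Imc1" stay whole
    return re.sub(r"(?<=[a-z])(?=[A-Z])", " ", base).split(" ")


def parse_feature_name(name: str) -> FeatureDescriptor:
    """Parse a space- or underscore-delimited feature name.

    Accepted shapes: ``<seq> <group> <base tokens...>`` for per-sequence
    features, and ``SHAPE [shape] <base tokens...>`` for geometry features.
    Base-name tokens are concatenated (``Dependence Non Uniformity
    Normalized`` -> ``DependenceNonUniformityNormalized``).
    """
    tokens = [t for t in re.split(r"[ _]+", name.strip()) if t]
    if not tokens:
        raise FeatureNameError("empty feature name")
    seq_token = tokens[0]
    if seq_token.upper() not in _SEQ_TOKENS:
        raise FeatureNameError(f"unknown sequence token {seq_token!r} in {name!r}")
    sequence = _SEQ_TOKENS[seq_token.upper()]
    rest = tokens[1:]
    if sequence == "SHAPE-global":
        if rest and rest[0].lower() == "shape":
            rest = rest[1:]
        group = "shape"
    else:
        if not rest:
            raise FeatureNameError(f"missing feature group in {name!r}")
        group_token = rest[0]
        if group_token.lower() not in GROUPS or group_token.lower() == "shape":
            raise FeatureNameError(f"unknown feature group token {group_token!r} in {name!r}")
        group = group_token.lower()
        rest = rest[1:]
    if not rest:
        raise FeatureNameError(f"missing feature base name in {name!r}")
    return FeatureDescriptor(sequence, group, "".join(rest))


def format_feature_name(descriptor: FeatureDescriptor) -> str:
    """Canonical underscore-joined form (inverse of :func:`parse_feature_name`)."""
    return descriptor.name


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered collection of feature descriptors with unique names."""

    descriptors: tuple[FeatureDescriptor, ...]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {d.name: i for i, d in enumerate(self.descriptors)}
        if len(index) != len(self.descriptors):
            raise FeatureNameError("duplicate feature descriptors in catalogue")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for d in self.descriptors:
            sizes[d.group] = sizes.get(d.group, 0) + 1
        return sizes

    def position(self, name: str) -> int:
        """Catalogue index of a canonical feature name (used for tie-breaks)."""
        try:
            return self._index[name]
        except KeyError:
            raise FeatureNameError(f"feature {name!r} not in catalogue") from None

    def subset(self, names: Iterable[str]) -> "FeatureCatalog":
        return FeatureCatalog(tuple(self.descriptors[self.position(n)] for n in names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [d.sequence for d in self.descriptors],
                "group": [d.group for d in self.descriptors],
                "base_name": [d.base_name for d in self.descriptors],
            }
        )

    def write(self, path: str | Path) -> None:
        """Export the catalogue as delimited text (sequence, group, base_name)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_default_catalog() -> FeatureCatalog:
    """The 386-feature default catalogue.

    Order is deterministic: SHAPE-global first, then sequences T2, ART,
    PORT, TARD; within a sequence the groups firstorder, glcm, glrlm,
    glszm, gldm, ngtdm; base names lexicographic within a group.
    """
    descriptors: list[FeatureDescriptor] = [
        FeatureDescriptor("SHAPE-global", "shape", b) for b in sorted(SHAPE_FEATURES)
    ]
    for seq in ("T2", "ART", "PORT", "TARD"):
        for group in _PER_SEQUENCE_GROUPS:
            descriptors.extend(
                FeatureDescriptor(seq, group, b) for b in sorted(_GROUP_FEATURES[group])
            )
    return FeatureCatalog(tuple(descriptors))


@dataclass
class FeatureTable:
    """VOIs x features numeric matrix with subject, tissue and grade labels.

    One row per VOI: an HCC lesion row carries the patient's histologic
    grade (G1/G2/G3); a healthy-tissue (HT) row from the same patient
    shares the subject id and carries grade ``NA``.
    """

    subject_ids: pd.Series
    tissue: pd.Series
    grade: pd.Series
    values: pd.DataFrame
    catalog: FeatureCatalog

    def __post_init__(self) -> None:
        n = len(self.values)
        for label, series in (
            ("subject_id", self.subject_ids),
            ("tissue", self.tissue),
            ("grade", self.grade),
        ):
            if len(series) != n:
                raise FeatureTableError(f"{label} length {len(series)} != {n} rows")
        if list(self.values.columns) != self.catalog.names:
            raise FeatureTableError("value columns do not match catalogue order")
        bad_tissue = set(self.tissue) - set(TISSUES)
        if bad_tissue:
            raise FeatureTableError(f"unknown tissue labels {sorted(bad_tissue)}")
        bad_grade = set(self.grade) - set(GRADES)
        if bad_grade:
            raise FeatureTableError(f"unknown grade labels {sorted(bad_grade)}")
        na_on_hcc = (self.grade.to_numpy() == "NA") & (self.tissue.to_numpy() == "HCC")
        if na_on_hcc.any():
            raise FeatureTableError("grade NA is only allowed on HT rows")
        if self.values.isna().to_numpy().any():
            raise MissingValueError("feature table contains missing values")
        dup = pd.DataFrame({"s": self.subject_ids, "t": self.tissue}).duplicated()
        if dup.any():
            pairs = sorted(
                {(s, t) for s, t in zip(self.subject_ids[dup], self.tissue[dup])}
            )
            raise FeatureTableError(f"duplicate (subject_id, tissue) rows: {pairs}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return self.catalog.names

    def subset_rows(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            self.subject_ids[mask].reset_index(drop=True),
            self.tissue[mask].reset_index(drop=True),
            self.grade[mask].reset_index(drop=True),
            self.values.loc[mask].reset_index(drop=True),
            self.catalog,
        )

    def check_pairing(self) -> None:
        """Require every HT row's subject to match exactly one HCC row.

        Raises :class:`PairingError` listing unmatched subjects otherwise.
        """
        hcc = set(self.subject_ids[self.tissue == "HCC"])
        ht = set(self.subject_ids[self.tissue == "HT"])
        unmatched = sorted(hcc.symmetric_difference(ht))
        if unmatched:
            raise PairingError(f"unpaired subjects: {unmatched}")


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_feature_table(path: str | Path, catalog: FeatureCatalog) -> FeatureTable:
    """Read a delimited feature table (CSV or TSV, auto-detected).

    The header must contain the reserved columns ``subject_id``, ``tissue``
    and ``grade`` plus one column per catalogue feature (either naming
    dialect). Unknown columns are dropped with a warning; missing or
    non-numeric cells raise :class:`MissingValueError` citing row and
    column.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first.rstrip("\n"))
    raw = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "tissue": str, "grade": str})
    for col in RESERVED_COLUMNS:
        if col not in raw.columns:
            raise FeatureTableError(f"missing reserved column {col!r}")

    canonical: dict[str, str] = {}
    unknown: list[str] = []
    for col in raw.columns:
        if col in RESERVED_COLUMNS:
            continue
        try:
            desc = parse_feature_name(col)
        except FeatureNameError:
            unknown.append(col)
            continue
        if desc.name in catalog:
            canonical[col] = desc.name
        else:
            unknown.append(col)
    if unknown:
        warnings.warn(f"ignoring {len(unknown)} unknown column(s): {unknown[:5]}...")
    missing = [n for n in catalog.names if n not in set(canonical.values())]
    if missing:
        raise FeatureTableError(
            f"{len(missing)} catalogue feature(s) missing from file, e.g. {missing[:3]}"
        )

    values = raw[list(canonical)].rename(columns=canonical)
    values = values[catalog.names]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(np.where(bad.any(axis=1))[0][0])
        col = bad.columns[int(np.where(bad.iloc[row])[0][0])]
        raise MissingValueError(f"missing or non-numeric value at row {row}, column {col!r}")
    grade = raw["grade"].fillna("NA").replace("", "NA")
    return FeatureTable(
        raw["subject_id"].astype(str).rename("subject_id"),
        raw["tissue"].astype(str).rename("tissue"),
        grade.astype(str).rename("grade"),
        numeric.astype(float),
        catalog,
    )


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = ",") -> None:
    """Write a feature table in canonical column order.

    Values are printed with 12 significant digits so a read/write cycle is
    value-identical at that precision.
    """
    out = pd.concat(
        [
            table.subject_ids.rename("subject_id"),
            table.tissue.rename("tissue"),
            table.grade.rename("grade"),
            table.values,
        ],
        axis=1,
    )
    out.to_csv(path, sep=sep, index=False, float_format="%.12g")
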