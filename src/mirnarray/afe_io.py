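"""Reading Agilent Feature Extraction (AFE) output and experiment target files.

AFE exports one tab-delimited text file per array, carrying per-spot raw and
background-corrected signals, AFE's own probe/gene summaries (TotalProbeSignal,
TotalGeneSignal), quality flags, and probe annotation.  Two dialects are
understood:

* *flat* — a single header row naming the columns, one row per spot;
* *blocked* — the multi-block vendor layout (FEPARAMS / STATS / FEATURES
  sections, each introduced by a TYPE row and terminated by ``*``); only the
  FEATURES block is read.

The experiment layout is a tab-delimited *target file* with the mandatory
columns ``FileName``, ``Treatment`` and ``GErep`` (an integer code per
treatment) plus optional covariate columns such as ``Subject``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_TARGET_COLUMNS = ("FileName", "Treatment", "GErep")

#: AFE feature columns that must be present in every data file.
REQUIRED_FEATURE_COLUMNS = (
    "gMeanSignal",
    "gProcessedSignal",
    "gTotalGeneSignal",
    "ProbeName",
    "GeneName",
    "ControlType",
)

#: Optional AFE columns and the sentinel used when a file lacks them.
OPTIONAL_FEATURE_COLUMNS: Mapping[str, float] = {
    "gTotalProbeSignal": np.nan,
    "gIsGeneDetected": 0,
    "gIsSaturated": 0,
    "gIsFeatNonUnifOL": 0,
    "gIsFeatPopnOL": 0,
    "gBGMedianSignal": np.nan,
    "gBGUsed": np.nan,
}

SIGNAL_COLUMNS = (
    "gMeanSignal",
    "gProcessedSignal",
    "gTotalProbeSignal",
    "gTotalGeneSignal",
    "gBGMedianSignal",
    "gBGUsed",
)
FLAG_COLUMNS = (
    "gIsGeneDetected",
    "gIsSaturated",
    "gIsFeatNonUnifOL",
    "gIsFeatPopnOL",
)

#: Canonical column order used when writing AFE-format files.
FEATURE_COLUMN_ORDER = REQUIRED_FEATURE_COLUMNS + tuple(OPTIONAL_FEATURE_COLUMNS)


class SchemaError(ValueError):
    """An input file does not conform to the expected column schema."""


@dataclass
class TargetTable:
    """Experiment layout: one row per array, in hybridization file order.

    ``GErep`` assigns each treatment a positive integer group code; the codes
    must form a contiguous set {1..G} and each treatment must map to exactly
    one code.  Additional columns are carried as covariates.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_TARGET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"target file is missing required column(s): {', '.join(missing)}")
        names = self.frame["FileName"]
        if names.duplicated().any():
            dup = names[names.duplicated()].iloc[0]
            raise SchemaError(f"duplicate FileName in target file: {dup!r}")
        if len(self.frame):
            ge = self.frame["GErep"].astype(int)
            levels = sorted(set(ge))
            if levels != list(range(1, len(levels) + 1)):
                raise SchemaError(f"GErep codes {levels} are not a contiguous set 1..G")
            mapping = self.frame.groupby("Treatment")["GErep"].nunique()
            if (mapping > 1).any():
                bad = mapping[mapping > 1].index[0]
                raise SchemaError(f"treatment {bad!r} maps to more than one GErep code")
            self.frame = self.frame.assign(GErep=ge)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def file_names(self) -> list[str]:
        return list(self.frame["FileName"])

    @property
    def treatments(self) -> list[str]:
        return [str(t) for t in self.frame["Treatment"]]

    @property
    def ge_rep(self) -> np.ndarray:
        return self.frame["GErep"].to_numpy(dtype=int)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.frame.columns if c not in REQUIRED_TARGET_COLUMNS]

    @property
    def n_groups(self) -> int:
        return int(self.frame["GErep"].max()) if len(self.frame) else 0

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class ProbeLevelDataset:
    """Spot-by-array signals, flags and annotation for a set of arrays.

    All matrices share shape (n_spots, n_arrays), with columns aligned to
    ``targets``.  ``control_type`` follows the AFE coding: 0 = miRNA gene
    feature, +1 = positive control, -1 = negative control.
    """

    probe_name: np.ndarray
    gene_name: np.ndarray
    control_type: np.ndarray
    mean_signal: np.ndarray
    processed_signal: np.ndarray
    total_probe_signal: np.ndarray
    total_gene_signal: np.ndarray
    is_gene_detected: np.ndarray
    is_saturated: np.ndarray
    is_nonunif_outlier: np.ndarray
    is_popn_outlier: np.ndarray
    bg_median: np.ndarray
    bg_used: np.ndarray
    targets: TargetTable
    metadata: dict = field(default_factory=dict)

    MATRIX_FIELDS = (
        "mean_signal",
        "processed_signal",
        "total_probe_signal",
        "total_gene_signal",
        "is_gene_detected",
        "is_saturated",
        "is_nonunif_outlier",
        "is_popn_outlier",
        "bg_median",
        "bg_used",
    )

    def __post_init__(self) -> None:
        shape = self.mean_signal.shape
        for name in self.MATRIX_FIELDS:
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"matrix {name} has shape {m.shape}, expected {shape}")
        if len(self.probe_name) != shape[0]:
            raise ValueError("annotation length does not match number of spots")
        if len(self.targets) != shape[1]:
            raise ValueError("target table length does not match number of arrays")

    @property
    def n_spots(self) -> int:
        return self.mean_signal.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.mean_signal.shape[1]

    @property
    def array_names(self) -> list[str]:
        return self.targets.file_names

    @property
    def is_control(self) -> np.ndarray:
        return self.control_type != 0

    def subset_spots(self, mask: np.ndarray) -> "ProbeLevelDataset":
        """Return a copy restricted to the spots selected by a boolean mask."""
        kwargs = {name: getattr(self, name)[mask] for name in self.MATRIX_FIELDS}
        return ProbeLevelDataset(
            probe_name=self.probe_name[mask],
            gene_name=self.gene_name[mask],
            control_type=self.control_type[mask],
            targets=self.targets,
            metadata=dict(self.metadata),
            **kwargs,
        )


def read_targets(path: str | Path) -> TargetTable:
    """Read a tab-delimited target file into a :class:`TargetTable`."""
    frame = pd.read_csv(path, sep="\t", dtype={"FileName": str, "Treatment": str})
    return TargetTable(frame)


def _feature_table_lines(path: Path) -> tuple[list[str], list[list[str]]]:
    """Return (header, rows) of the FEATURES table for either AFE dialect."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty file")
    first = lines[0].split("\t")[0]
    if first in ("TYPE", "FEPARAMS", "STATS", "FEATURES"):
        # blocked dialect: locate the FEATURES header, consume DATA rows
        header: list[str] | None = None
        rows: list[list[str]] = []
        in_features = False
        for ln in lines:
            cells = ln.split("\t")
            tag = cells[0]
            if tag == "FEATURES":
                header = cells[1:]
                in_features = True
            elif tag == "DATA" and in_features:
                rows.append(cells[1:])
            elif tag == "*":
                in_features = False
        if header is None:
            raise SchemaError(f"{path}: blocked AFE file has no FEATURES block")
        return header, rows
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    return header, rows


def _is_number(cell: str) -> bool:
    if cell == "":
        return True
    try:
        float(cell)
    except ValueError:
        return False
    return True


def read_afe_features(path: str | Path) -> pd.DataFrame:
    """Read one AFE feature-extraction file into a per-spot DataFrame.

    Handles both the flat and the blocked dialect.  Missing optional columns
    are filled with a sentinel and logged; unknown columns are ignored.
    """
    path = Path(path)
    header, rows = _feature_table_lines(path)
    frame = pd.DataFrame(rows, columns=header)

    missing_req = [c for c in REQUIRED_FEATURE_COLUMNS if c not in frame.columns]
    if missing_req:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing_req)}")
    unknown = [c for c in frame.columns if c not in FEATURE_COLUMN_ORDER]
    if unknown:
        logger.info("%s: ignoring %d unknown column(s): %s", path.name, len(unknown), ", ".join(unknown))

    out = pd.DataFrame(index=frame.index)
    out["ProbeName"] = frame["ProbeName"].astype(str)
    out["GeneName"] = frame["GeneName"].astype(str)
    numeric_cols = ("ControlType",) + SIGNAL_COLUMNS + FLAG_COLUMNS
    for col in numeric_cols:
        if col not in frame.columns:
            sentinel = OPTIONAL_FEATURE_COLUMNS[col]
            logger.warning("%s: column %s absent; filled with sentinel %r", path.name, col, sentinel)
            out[col] = sentinel
            continue
        raw = frame[col].astype(str).str.strip()
        # float() rather than the fast pandas parser: round-trips repr output
        # bit-exactly
        def parse(cell: str) -> float:
            if cell == "":
                return np.nan
            return float(cell)

        try:
            values = raw.map(parse)
        except ValueError:
            bad = raw.map(lambda c: not _is_number(c))
            idx = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {raw[idx]!r} in column {col}, row {idx}"
            ) from None
        out[col] = values.astype(float)
    out["ControlType"] = out["ControlType"].astype(int)
    for col in FLAG_COLUMNS:
        out[col] = (out[col].fillna(0) != 0).astype(int)
    return out


def assemble_dataset(
    targets: TargetTable,
    records: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
) -> ProbeLevelDataset:
    """Combine per-array feature records into a :class:`ProbeLevelDataset`.

    ``records`` maps target file names to the output of
    :func:`read_afe_features` (or is a sequence in target order).  All arrays
    must share an identical ProbeName sequence; annotation is taken from the
    first array and matrix columns follow target-table row order.
    """
    if isinstance(records, Mapping):
        missing = [f for f in targets.file_names if f not in records]
        if missing:
            raise ValueError(f"no feature records for target file(s): {', '.join(missing)}")
        ordered = [records[f] for f in targets.file_names]
    else:
        ordered = list(records)
        if len(ordered) != len(targets):
            raise ValueError(f"{len(ordered)} feature tables for {len(targets)} target rows")
    if not ordered:
        raise ValueError("cannot assemble a dataset from zero arrays")

    ref = ordered[0]
    ref_probes = ref["ProbeName"].to_numpy()
    for name, frame in zip(targets.file_names, ordered):
        probes = frame["ProbeName"].to_numpy()
        if len(probes) != len(ref_probes):
            raise ValueError(
                f"array {name!r} has {len(probes)} spots, expected {len(ref_probes)}"
            )
        neq = probes != ref_probes
        if neq.any():
            i = int(np.argmax(neq))
            raise ValueError(
                f"array {name!r} spot {i} has probe {probes[i]!r}, expected {ref_probes[i]!r}"
            )

    def stack(col: str, dtype) -> np.ndarray:
        return np.column_stack([f[col].to_numpy(dtype=dtype) for f in ordered])

    return ProbeLevelDataset(
        probe_name=ref_probes.astype(str),
        gene_name=ref["GeneName"].to_numpy(dtype=str),
        control_type=ref["ControlType"].to_numpy(dtype=int),
        mean_signal=stack("gMeanSignal", float),
        processed_signal=stack("gProcessedSignal", float),
        total_probe_signal=stack("gTotalProbeSignal", float),
        total_gene_signal=stack("gTotalGeneSignal", float),
        is_gene_detected=stack("gIsGeneDetected", int),
        is_saturated=stack("gIsSaturated", int),
        is_nonunif_outlier=stack("gIsFeatNonUnifOL", int),
        is_popn_outlier=stack("gIsFeatPopnOL", int),
        bg_median=stack("gBGMedianSignal", float),
        bg_used=stack("gBGUsed", float),
        targets=targets,
    )


def read_dataset(targets_path: str | Path, data_dir: str | Path) -> ProbeLevelDataset:
    """Read a target file plus its AFE data files from one directory."""
    targets = read_targets(targets_path)
    data_dir = Path(data_dir)
    records = {f: read_afe_features(data_dir / f) for f in targets.file_names}
    return assemble_dataset(targets, records)
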