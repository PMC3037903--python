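"""Synthetic AFE-format datasets with known ground truth.

The generator emulates the Agilent Human miRNA Microarray v2.0 layout: 723
human and 76 viral miRNA genes, of which 362/45/390/2 are interrogated by
2/3/4/1 distinct probes, every miRNA gene occupying 16 spots; positive
controls occupy 20 spots over 4 probes; negative controls populate a block of
near-background spots.  Probe-level raw signals follow the additive model the
RMA summarization assumes,

    log2 mean_signal = baseline(gene) + effect(gene, group)
                       + affinity(probe) + noise,

with probe affinities summing to zero within each gene, so that configured
group effects are exactly recoverable from noise-free data.  AFE's processed
signal is the raw signal minus a per-array background (constant plus a small
spatial gradient), and its TotalProbeSignal / TotalGeneSignal summaries are
recomputed from the processed signal exactly as the image software defines
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .afe_io import FEATURE_COLUMN_ORDER, ProbeLevelDataset, TargetTable

# v2.0 composition: genes per probe-multiplicity class, in class order 2/3/4/1
V2_CLASS_COUNTS = {2: 362, 3: 45, 4: 390, 1: 2}
V2_HUMAN_GENES = 723
V2_VIRAL_GENES = 76
SPOTS_PER_GENE = 16
POS_CONTROL_SPOTS = 20
POS_CONTROL_PROBES = 4

#: Replicate allocation per probe-multiplicity class (16 spots each; the
#: 3-probe class uses the closest-to-even split 6/5/5).
REPLICATE_SPLITS = {1: (16,), 2: (8, 8), 3: (6, 5, 5), 4: (4, 4, 4, 4)}


@dataclass
class GeneDesign:
    gene_name: str
    species_class: str  # human | viral | pos_control | neg_control
    probe_names: list[str]
    replicates_per_probe: list[int]

    @property
    def n_spots(self) -> int:
        return sum(self.replicates_per_probe)


@dataclass
class ArrayDesign:
    """The physical layout: genes, their probes and replicate counts."""

    genes: list[GeneDesign]

    @property
    def control_genes(self) -> list[GeneDesign]:
        return [g for g in self.genes if g.species_class in ("pos_control", "neg_control")]

    @property
    def mirna_genes(self) -> list[GeneDesign]:
        return [g for g in self.genes if g.species_class in ("human", "viral")]

    def spot_table(self) -> pd.DataFrame:
        """One row per spot: probe/gene annotation and AFE control coding."""
        code = {"human": 0, "viral": 0, "pos_control": 1, "neg_control": -1}
        rows = []
        for g in self.genes:
            for probe, reps in zip(g.probe_names, g.replicates_per_probe):
                for _ in range(reps):
                    rows.append((probe, g.gene_name, code[g.species_class]))
        return pd.DataFrame(rows, columns=["ProbeName", "GeneName", "ControlType"])


def make_array_design(
    class_counts: Mapping[int, int] | None = None,
    n_human: int = V2_HUMAN_GENES,
    n_viral: int = V2_VIRAL_GENES,
    n_pos_controls: int = 10,
    n_neg_probes: int = 10,
    neg_replicates: int = 20,
) -> ArrayDesign:
    """Build an array design; defaults reproduce the v2.0 composition.

    ``class_counts`` maps probe multiplicity (1..4) to the number of miRNA
    genes in that class; the counts must sum to ``n_human + n_viral``.
    """
    if class_counts is None:
        class_counts = dict(V2_CLASS_COUNTS)
    class_counts = {k: int(v) for k, v in class_counts.items() if v}
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("class counts must be nonnegative")
    total = sum(class_counts.values())
    if total != n_human + n_viral:
        raise ValueError(
            f"probe-class counts sum to {total}, but n_human + n_viral = {n_human + n_viral}"
        )

    genes: list[GeneDesign] = []
    idx = 0
    for n_probes in sorted(class_counts):
        for _ in range(class_counts[n_probes]):
            if idx < n_human:
                name = f"hsa-miR-{idx + 1:04d}"
                species = "human"
            else:
                name = f"hsv-miR-{idx - n_human + 1:04d}"
                species = "viral"
            split = REPLICATE_SPLITS[n_probes]
            probes = [f"A_25_P{idx + 1:05d}{chr(ord('a') + k)}" for k in range(n_probes)]
            genes.append(GeneDesign(name, species, probes, list(split)))
            idx += 1

    for p in range(n_pos_controls):
        probes = [f"PC_{p + 1:03d}{chr(ord('a') + k)}" for k in range(POS_CONTROL_PROBES)]
        genes.append(GeneDesign(f"pos_ctrl_{p + 1:03d}", "pos_control", probes, [5, 5, 5, 5]))
    for p in range(n_neg_probes):
        genes.append(
            GeneDesign("neg_ctrl", "neg_control", [f"NC_{p + 1:03d}"], [neg_replicates])
        )
    return ArrayDesign(genes)


@dataclass
class SimulationConfig:
    """Parameters of the generative model for synthetic probe signals.

    Scales are log2 for means/effects/noise and linear intensity units for
    backgrounds and negative controls.  The default layout reproduces the
    canonical 6-array experiment: treatments A/B/C with two subjects each.
    """

    seed: int = 0
    treatments: Sequence[str] = ("A", "A", "B", "B", "C", "C")
    subjects: Sequence[int] = (1, 2, 1, 2, 1, 2)
    baseline_mean: float = 9.0  # log2 center of gene baselines
    baseline_sd: float = 1.5
    affinity_sd: float = 0.7  # probe affinity spread (zero-sum per gene)
    noise_sd: float = 0.1  # replicate-level log2 noise
    n_spikein: int = 20
    spike_effect: float = 2.0  # log2 fold change of spiked genes
    spike_groups: Sequence[str] = ("B", "C")
    spikein_effects: Mapping[str, Mapping[str, float]] | None = None
    bg_mean: float = 30.0  # per-array background level, linear scale
    bg_sd: float = 5.0
    bg_gradient: float = 10.0  # background drift across the array surface
    negctrl_mean: float = 40.0  # raw negative-control intensity
    negctrl_sd: float = 8.0
    detection_fold: float = 3.0  # signal-to-error ratio for the detection flag

    def __post_init__(self) -> None:
        if len(self.treatments) != len(self.subjects):
            raise ValueError("treatments and subjects must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.negctrl_sd <= 0 or self.bg_sd < 0:
            raise ValueError("negative-control sd must be positive")

    @property
    def n_arrays(self) -> int:
        return len(self.treatments)

    @property
    def group_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.treatments:
            seen.setdefault(t, None)
        return list(seen)

    def target_table(self) -> TargetTable:
        levels = self.group_levels
        ge = [levels.index(t) + 1 for t in self.treatments]
        counts: dict[str, int] = {}
        names = []
        for t in self.treatments:
            counts[t] = counts.get(t, 0) + 1
            names.append(f"msc{t}{counts[t]}.txt")
        return TargetTable(
            pd.DataFrame(
                {
                    "FileName": names,
                    "Treatment": list(self.treatments),
                    "GErep": ge,
                    "Subject": list(self.subjects),
                }
            )
        )


def _spike_table(design: ArrayDesign, config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Map gene -> {group: log2 effect} for the spike-in set."""
    if config.spikein_effects is not None:
        return {g: dict(v) for g, v in config.spikein_effects.items()}
    mirna = [g.gene_name for g in design.mirna_genes]
    n = min(config.n_spikein, len(mirna))
    if n == 0:
        return {}
    chosen = rng.choice(len(mirna), size=n, replace=False)
    groups = [g for g in config.spike_groups if g in config.group_levels]
    effects: dict[str, dict[str, float]] = {}
    for k, i in enumerate(sorted(chosen)):
        if groups:
            effects[mirna[i]] = {groups[k % len(groups)]: config.spike_effect}
    return effects


def simulate_probe_signals(design: ArrayDesign, config: SimulationConfig) -> ProbeLevelDataset:
    """Draw a probe-level dataset from the additive log2 signal model.

    The returned dataset carries the realized per-gene/group log2 effects in
    ``metadata["ground_truth"]`` (a DataFrame gene x group).
    """
    rng = np.random.default_rng(config.seed)
    spots = design.spot_table()
    n_spots = len(spots)
    n_arrays = config.n_arrays
    targets = config.target_table()
    levels = config.group_levels
    group_of_array = [levels.index(t) for t in config.treatments]

    gene_names = [g.gene_name for g in design.genes]
    baselines = {}
    affinities: dict[str, float] = {}
    for g in design.genes:
        if g.species_class == "neg_control":
            continue
        if g.species_class == "pos_control":
            # bright-or-dim non-miRNA probes; drawn from the same range
            baselines[g.gene_name] = config.baseline_mean + rng.normal(0.0, config.baseline_sd)
        else:
            baselines[g.gene_name] = rng.normal(config.baseline_mean, config.baseline_sd)
        aff = rng.normal(0.0, config.affinity_sd, size=len(g.probe_names))
        aff -= aff.mean()  # zero-sum within gene: affinities are identifiable only up to this
        if len(g.probe_names) == 1:
            aff[:] = 0.0
        for probe, a in zip(g.probe_names, aff):
            affinities[probe] = float(a)

    spikes = _spike_table(design, config, rng)
    effect = np.zeros((len(design.genes), len(levels)))
    for gi, g in enumerate(design.genes):
        for grp, e in spikes.get(g.gene_name, {}).items():
            effect[gi, levels.index(grp)] = e

    gene_index = {g.gene_name: i for i, g in enumerate(design.genes)}
    spot_gene = spots["GeneName"].map(gene_index).to_numpy()
    spot_is_neg = (spots["ControlType"] == -1).to_numpy()
    spot_base = np.array(
        [baselines.get(g, 0.0) for g in spots["GeneName"]], dtype=float
    )
    spot_aff = np.array([affinities.get(p, 0.0) for p in spots["ProbeName"]], dtype=float)

    noise = rng.normal(0.0, config.noise_sd, size=(n_spots, n_arrays)) if config.noise_sd > 0 else np.zeros((n_spots, n_arrays))
    log2_signal = (
        spot_base[:, None]
        + spot_aff[:, None]
        + effect[spot_gene][:, group_of_array]
        + noise
    )
    mean_signal = np.power(2.0, log2_signal)

    # negative controls: near-background raw intensities, no gene structure
    neg_draw = rng.normal(config.negctrl_mean, config.negctrl_sd, size=(n_spots, n_arrays))
    mean_signal[spot_is_neg] = np.maximum(neg_draw[spot_is_neg], 1.0)

    # background used by AFE: per-array constant plus a gradient over spot index
    bg_level = rng.normal(config.bg_mean, config.bg_sd, size=n_arrays)
    gradient = config.bg_gradient * (np.arange(n_spots) / max(n_spots - 1, 1))
    bg_used = np.maximum(bg_level[None, :] + gradient[:, None], 0.0)
    bg_median = np.maximum(bg_used - 0.5 * config.bg_gradient, 0.0)

    processed = mean_signal - bg_used

    dataset = ProbeLevelDataset(
        probe_name=spots["ProbeName"].to_numpy(dtype=str),
        gene_name=spots["GeneName"].to_numpy(dtype=str),
        control_type=spots["ControlType"].to_numpy(dtype=int),
        mean_signal=mean_signal,
        processed_signal=processed,
        total_probe_signal=np.zeros_like(processed),
        total_gene_signal=np.zeros_like(processed),
        is_gene_detected=np.zeros((n_spots, n_arrays), dtype=int),
        is_saturated=np.zeros((n_spots, n_arrays), dtype=int),
        is_nonunif_outlier=np.zeros((n_spots, n_arrays), dtype=int),
        is_popn_outlier=np.zeros((n_spots, n_arrays), dtype=int),
        bg_median=bg_median,
        bg_used=bg_used,
        targets=targets,
    )
    dataset = compute_afe_summaries(dataset)
    _set_detection_flags(dataset, config)

    truth = pd.DataFrame(effect, index=gene_names, columns=levels)
    truth = truth.loc[[g.gene_name for g in design.mirna_genes]]
    dataset.metadata["ground_truth"] = truth
    dataset.metadata["config"] = config
    return dataset


def _set_detection_flags(dataset: ProbeLevelDataset, config: SimulationConfig) -> None:
    """Flag a gene detected on an array when its brightest probe-level
    processed signal exceeds ``detection_fold`` times the array's noise scale
    (the spread of its negative-control processed signals)."""
    neg = dataset.control_type == -1
    if neg.any():
        noise_scale = dataset.processed_signal[neg].std(axis=0, ddof=1)
    else:
        noise_scale = np.full(dataset.n_arrays, config.negctrl_sd)
    frame = pd.DataFrame(dataset.processed_signal)
    frame["probe"] = dataset.probe_name
    frame["gene"] = dataset.gene_name
    probe_level = frame.groupby(["gene", "probe"], sort=False).mean()
    gene_max = probe_level.groupby(level="gene", sort=False).max()
    detected = gene_max.to_numpy() > config.detection_fold * noise_scale[None, :]
    det_by_gene = dict(zip(gene_max.index, detected.astype(int)))
    for i, g in enumerate(dataset.gene_name):
        dataset.is_gene_detected[i, :] = det_by_gene[g]


def compute_afe_summaries(dataset: ProbeLevelDataset) -> ProbeLevelDataset:
    """Fill TotalProbeSignal and TotalGeneSignal from the processed signal.

    TPS(probe) = mean of the probe's background-subtracted replicate signals
    times the replicate count (i.e. their sum), written to every replicate
    spot.  TGS(gene) = sum of the gene's distinct-probe TPS values, written to
    every spot of the gene.
    """
    if dataset.n_spots == 0:
        raise ValueError("dataset has no spots")
    frame = pd.DataFrame(dataset.processed_signal)
    probe = pd.Series(dataset.probe_name)
    gene = pd.Series(dataset.gene_name)
    tps = frame.groupby(probe, sort=False).transform("sum")
    probe_level = frame.copy()
    probe_level["__probe"] = probe.to_numpy()
    probe_level["__gene"] = gene.to_numpy()
    per_probe = probe_level.groupby(["__gene", "__probe"], sort=False).sum()
    per_gene = per_probe.groupby(level="__gene", sort=False).sum()
    tgs = per_gene.reindex(gene).to_numpy()
    dataset.total_probe_signal = tps.to_numpy()
    dataset.total_gene_signal = tgs
    return dataset


def _format_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = [repr(float(v)) for v in out[col]]
    return out


def write_afe_files(
    dataset: ProbeLevelDataset,
    out_dir: str | Path,
    dialect: str = "flat",
) -> list[Path]:
    """Write one AFE-format file per array plus the matching target file.

    ``dialect="flat"`` writes a single header row; ``dialect="blocked"``
    writes the vendor-style FEPARAMS/STATS/FEATURES sections.  Floats are
    written with full repr so a read-back reproduces every matrix bit-exactly.
    Returns the written data-file paths; the target file is ``targets.txt``.
    """
    if dataset.n_spots == 0 or dataset.n_arrays == 0:
        raise ValueError("cannot write an empty dataset")
    if dialect not in ("flat", "blocked"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix_of = {
        "gMeanSignal": dataset.mean_signal,
        "gProcessedSignal": dataset.processed_signal,
        "gTotalProbeSignal": dataset.total_probe_signal,
        "gTotalGeneSignal": dataset.total_gene_signal,
        "gIsGeneDetected": dataset.is_gene_detected,
        "gIsSaturated": dataset.is_saturated,
        "gIsFeatNonUnifOL": dataset.is_nonunif_outlier,
        "gIsFeatPopnOL": dataset.is_popn_outlier,
        "gBGMedianSignal": dataset.bg_median,
        "gBGUsed": dataset.bg_used,
    }
    paths = []
    for j, fname in enumerate(dataset.targets.file_names):
        cols: dict[str, object] = {
            "ProbeName": dataset.probe_name,
            "GeneName": dataset.gene_name,
            "ControlType": dataset.control_type,
        }
        for name, m in matrix_of.items():
            cols[name] = m[:, j]
        frame = _format_frame(pd.DataFrame(cols)[list(FEATURE_COLUMN_ORDER)])
        path = out_dir / fname
        if dialect == "flat":
            frame.to_csv(path, sep="\t", index=False)
        else:
            _write_blocked(frame, path)
        paths.append(path)
    dataset.targets.write(out_dir / "targets.txt")
    truth = dataset.metadata.get("ground_truth")
    if truth is not None:
        truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index_label="GeneName")
    return paths


def _write_blocked(frame: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("TYPE\ttext\ttext\n")
        fh.write("FEPARAMS\tProtocol_Name\tScan_Date\n")
        fh.write("DATA\tmiRNA_v2\tNA\n")
        fh.write("*\n")
        fh.write("TYPE\tfloat\n")
        fh.write("STATS\tgDarkOffsetAverage\n")
        fh.write("DATA\t0.0\n")
        fh.write("*\n")
        fh.write("TYPE" + "\ttext" * len(frame.columns) + "\n")
        fh.write("FEATURES\t" + "\t".join(frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("DATA\t" + "\t".join(str(v) for v in row) + "\n")
        fh.write("*\n")
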