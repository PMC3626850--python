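"""Synthetic probe-intensity datasets with known ground truth.

The generator emulates the study design the pipeline is built for: three
neuroblastoma cell lines (SK-N-BE, LAN-5, SH-SY5Y), each untreated and
ATRA-treated with two biological repeats — 12 arrays in total — measured on a
strand-specific tiling design.  Probe intensities follow a log-normal model

    intensity(p, s) = 2 ** (x[t(p), s] + a_p + eps_ps)

where ``x`` is the transcript-level log2 signal of the transcript (or host
gene, or background) the probe interrogates, ``a_p`` a per-probe affinity,
and ``eps`` measurement noise.  Transcript signals carry a per-cell-line and
a per-array biological deviation; for intragenic regions the deviations of
the two T-UCR strand transcripts and of the host-gene exonic signal are
drawn from a correlated Gaussian so that the planted T-UCR/host correlation
is exact at the signal level.  Treatment adds a planted log2 fold change to
the treated arrays of differentially expressed (DE) transcripts.  Isolated
probe outliers are multiplicative spikes — exactly what window-3 median
smoothing is meant to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SAMPLE_COLUMNS, IntensityMatrix, transcript_id
from .probes import CONTAINER_STRAND, CONTAINERS, design_probes, exon_probe_map
from .regions import (ExonAnnotation, UCRegion, read_exons, read_regions,
                      regions_to_frame, write_exons, write_regions)

CELL_LINES = ("SK-N-BE", "LAN-5", "SH-SY5Y")
_LINE_TAG = {"SK-N-BE": "SKNBE", "LAN-5": "LAN5", "SH-SY5Y": "SHSY5Y"}

TRUTH_COLUMNS = [
    "transcript", "region", "container", "region_class", "orientation",
    "host_gene", "planted_log2_fold", "de_label", "planted_rho", "outlier_probes",
]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults encode the emulated study conditions: 16 up- and 16
    down-regulated transcripts planted with fold changes of at least 1.5,
    and host-gene correlations of 0.68 for exonic sense T-UCRs and 0.13 for
    intronic antisense T-UCRs (0.4 for the remaining intragenic classes).
    Log2-scale noise magnitudes are design choices, not published biology.
    """

    n_regions: int = 200
    class_fractions: dict = field(default_factory=lambda: {
        "intergenic": 0.39, "intronic": 0.43, "exonic": 0.15, "partly_exonic": 0.03,
    })
    n_de_up: int = 16
    n_de_down: int = 16
    de_log2fold_range: tuple[float, float] = (math.log2(1.5), 2.0)
    rho_by_class: dict = field(default_factory=lambda: {
        "exonic_sense": 0.68, "intronic_antisense": 0.13,
    })
    default_rho: float = 0.4
    probe_affinity_sd: float = 0.5
    noise_sd: float = 0.3
    line_sd: float = 0.5          # per-transcript, per-cell-line biological shift
    repeat_sd: float = 0.6        # per biological repeat, shared treated/untreated
    array_sd: float = 0.2         # per-array residual (treatment-response noise)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    de_baseline_boost: float = 2.0  # keeps planted DE transcripts above background
    host_baseline_mean: float = 9.0
    host_baseline_sd: float = 0.5
    background_level: float = 6.0
    outlier_prob: float = 0.01
    outlier_scale: float = 8.0
    region_length_range: tuple[int, int] = (200, 600)
    step: int = 45
    tm_target: float = 74.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.n_de_up + self.n_de_down > 2 * self.n_regions:
            raise ValueError("more planted DE transcripts than transcripts")
        for name in ("probe_affinity_sd", "noise_sd", "line_sd", "repeat_sd",
                     "array_sd", "baseline_sd", "host_baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must lie in [0, 1]")
        if self.outlier_scale <= 0:
            raise ValueError("outlier_scale must be positive")
        for rho in list(self.rho_by_class.values()) + [self.default_rho]:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("planted correlations must lie in [-1, 1]")
        if self.de_log2fold_range[0] > self.de_log2fold_range[1]:
            raise ValueError("empty de_log2fold_range")


@dataclass
class SimulatedDataset:
    """Everything downstream stages need, plus the planted ground truth."""

    regions: list[UCRegion]
    exons: list[ExonAnnotation]
    probes: pd.DataFrame
    intensities: IntensityMatrix
    truth: pd.DataFrame
    probe_gene_map: dict[str, str]


def make_sample_sheet() -> pd.DataFrame:
    rows = [
        {
            "array_id": f"{_LINE_TAG[line]}_{'ATRA' if treated else 'untreated'}_{rep}",
            "cell_line": line,
            "treatment": "ATRA" if treated else "untreated",
            "repeat": rep,
        }
        for line in CELL_LINES
        for treated in (False, True)
        for rep in (1, 2)
    ]
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS).set_index("array_id")


def _class_counts(fractions: dict, n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n regions over the classes."""
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rest = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rest]:
        counts[k] += 1
    return counts


def _orientation(container: str, region: UCRegion) -> str:
    if not region.is_intragenic:
        return "n/a"
    return "sense" if CONTAINER_STRAND[container] == region.host_strand else "anti-sense"


def corr_class(region_class: str, orientation: str) -> str:
    return f"{region_class}_{'antisense' if orientation == 'anti-sense' else 'sense'}"


def simulate_dataset(config: SimConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate one reproducible dataset (regions, probes, intensities, truth)."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = make_sample_sheet()
    n_arrays = len(samples)
    line_of = samples["cell_line"].to_numpy()
    treated = (samples["treatment"] == "ATRA").to_numpy()
    line_index = np.array([CELL_LINES.index(l) for l in line_of])
    # biological repeat pairs: treated and untreated arrays of the same
    # (line, repeat) culture share one biological deviation
    pair_keys = list(dict.fromkeys(zip(line_of, samples["repeat"])))
    pair_index = np.array([pair_keys.index(k)
                           for k in zip(line_of, samples["repeat"])])
    n_pairs = len(pair_keys)

    # --- regions and host exons -------------------------------------------
    counts = _class_counts(config.class_fractions, config.n_regions)
    classes = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(classes)
    lo, hi = config.region_length_range
    regions: list[UCRegion] = []
    exons: list[ExonAnnotation] = []
    cursor = 5000
    for i, cls in enumerate(classes):
        length = int(rng.integers(lo, hi + 1))
        start, end = cursor, cursor + length
        cursor = end + 5000  # keep windows of neighbouring regions disjoint
        rid = f"sim.{i:04d}"
        if cls == "intergenic":
            regions.append(UCRegion(rid, "chrS", start, end, cls))
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene = f"G{i:04d}"
        regions.append(UCRegion(rid, "chrS", start, end, cls, gene, strand))
        # one 300 bp host exon in the upstream flank, inside the tiled window
        if strand == "+":
            exon = (start - 2200, start - 1900)
        else:
            exon = (end + 1900, end + 2200)
        exons.append(ExonAnnotation(gene, "chrS", strand, [exon]))

    probes = design_probes(regions, step=config.step, tm_target=config.tm_target)
    gene_map = exon_probe_map(probes, regions, exons)

    # --- planted truth -----------------------------------------------------
    transcripts = [(r, c) for r in regions for c in CONTAINERS]
    tids = [transcript_id(r.id, c) for r, c in transcripts]
    n_t = len(tids)
    de_idx = rng.choice(n_t, size=config.n_de_up + config.n_de_down, replace=False)
    lof, hif = config.de_log2fold_range
    delta = np.zeros(n_t)
    label = np.array(["null"] * n_t, dtype=object)
    for j, idx in enumerate(de_idx):
        mag = rng.uniform(lof, hif)
        if j < config.n_de_up:
            delta[idx], label[idx] = mag, "up"
        else:
            delta[idx], label[idx] = -mag, "down"

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_t)
    baseline[delta != 0] = rng.normal(
        config.baseline_mean + config.de_baseline_boost, config.baseline_sd / 2,
        size=len(de_idx),
    )

    # --- transcript-level signals over the 12 arrays -----------------------
    # Each biological deviation has a per-line, a per-repeat-pair (shared by
    # the paired treated/untreated arrays, hence cancelling in folds) and a
    # per-array component; every component of an intragenic transcript is
    # mixed with the host gene's matching component at the planted rho, so
    # the transcript/host correlation equals rho regardless of variance split.
    dims = (len(CELL_LINES), n_pairs, n_arrays)
    sds = (config.line_sd, config.repeat_sd, config.array_sd)

    def fresh_z():
        return tuple(rng.standard_normal(d) for d in dims)

    def combine(zs):
        zl, zp, za = zs
        return (sds[0] * zl[line_index] + sds[1] * zp[pair_index] + sds[2] * za)

    def mixed(z_shared, rho):
        mix = math.sqrt(max(0.0, 1.0 - rho ** 2))
        return tuple(rho * zs + mix * zf for zs, zf in zip(z_shared, fresh_z()))

    signal = np.zeros((n_t, n_arrays))
    host_signal: dict[str, np.ndarray] = {}
    planted_rho = np.full(n_t, np.nan)
    t_index = {tid: i for i, tid in enumerate(tids)}
    for r in regions:
        if r.is_intragenic:
            z_host = fresh_z()
            host_mu = rng.normal(config.host_baseline_mean, config.host_baseline_sd)
            host_signal[r.host_gene] = host_mu + combine(z_host)
        for c in CONTAINERS:
            i = t_index[transcript_id(r.id, c)]
            if r.is_intragenic:
                rho = config.rho_by_class.get(
                    corr_class(r.region_class, _orientation(c, r)), config.default_rho
                )
                planted_rho[i] = rho
                dev = combine(mixed(z_host, rho))
            else:
                dev = combine(fresh_z())
            signal[i] = baseline[i] + dev + delta[i] * treated

    # --- probe-level log2 values ------------------------------------------
    n_p = len(probes)
    probe_tid = np.array([transcript_id(r, c)
                          for r, c in zip(probes["region"], probes["container"])])
    is_core = (probes["zone"] == "core").to_numpy()
    probe_gene = np.array([gene_map.get(pid, "") for pid in probes["probe_id"]])

    log2v = np.full((n_p, n_arrays), config.background_level)
    core_rows = np.where(is_core)[0]
    log2v[core_rows] = signal[[t_index[t] for t in probe_tid[core_rows]]]
    exon_rows = np.where(probe_gene != "")[0]
    log2v[exon_rows] = np.array([host_signal[g] for g in probe_gene[exon_rows]])

    affinity = rng.normal(0.0, config.probe_affinity_sd, size=n_p)
    noise = rng.normal(0.0, config.noise_sd, size=(n_p, n_arrays))
    log2v = log2v + affinity[:, None] + noise
    outliers = rng.random((n_p, n_arrays)) < config.outlier_prob
    log2v[outliers] += math.log2(config.outlier_scale)

    intensities = IntensityMatrix(
        values=pd.DataFrame(
            np.exp2(log2v),
            index=pd.Index(probes["probe_id"].to_numpy(), name="probe_id"),
            columns=samples.index,
        ),
        samples=samples,
    )

    # --- truth table -------------------------------------------------------
    outlier_by_t: dict[str, set[str]] = {}
    pid_arr = probes["probe_id"].to_numpy()
    for p_i, _ in zip(*np.where(outliers)):
        outlier_by_t.setdefault(probe_tid[p_i], set()).add(pid_arr[p_i])
    rows = []
    for (r, c), tid in zip(transcripts, tids):
        i = t_index[tid]
        rows.append({
            "transcript": tid, "region": r.id, "container": c,
            "region_class": r.region_class,
            "orientation": _orientation(c, r),
            "host_gene": r.host_gene or "0",
            "planted_log2_fold": delta[i],
            "de_label": label[i],
            "planted_rho": planted_rho[i],
            "outlier_probes": ";".join(sorted(outlier_by_t.get(tid, ()))),
        })
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SimulatedDataset(regions, exons, probes, intensities, truth, gene_map)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the dataset as re-readable headered TSV/BED files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_regions(dataset.regions, out / "regions.tsv")
    write_exons(dataset.exons, out / "exons.bed")
    dataset.probes.to_csv(out / "probes.tsv", sep="\t", index=False)
    dataset.intensities.values.to_csv(
        out / "intensities.tsv", sep="\t", index_label="probe_id",
        float_format="%.17g",
    )
    dataset.intensities.samples.to_csv(out / "samples.tsv", sep="\t")
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                         float_format="%.17g")


def read_dataset(in_dir: str | Path) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    regions = read_regions(d / "regions.tsv")
    exons = read_exons(d / "exons.bed")
    probes = pd.read_csv(d / "probes.tsv", sep="\t")
    values = pd.read_csv(d / "intensities.tsv", sep="\t", index_col="probe_id")
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col="array_id")
    truth = pd.read_csv(d / "truth.tsv", sep="\t",
                        keep_default_na=False, na_values=[])
    truth["planted_rho"] = pd.to_numeric(truth["planted_rho"], errors="coerce")
    gene_map = exon_probe_map(probes, regions, exons)
    return SimulatedDataset(
        regions, exons, probes,
        IntensityMatrix(values=values, samples=samples),
        truth, gene_map,
    )


# ---------------------------------------------------------------------------
# gene-level expression generator for the knockdown-vs-ATRA overlap stage
# ---------------------------------------------------------------------------

@dataclass
class GeneSimConfig:
    """Planted scenario for the gene-array overlap analysis.

    Defaults plant the emulated study outcome: 150 genes up- and 123 genes
    down-regulated by the knockdown, of which 46 and 23 respectively change
    the same way under ATRA.
    """

    n_genes: int = 3000
    kd_up: int = 150
    kd_down: int = 123
    shared_up: int = 46
    shared_down: int = 23
    atra_extra_up: int = 150
    atra_extra_down: int = 100
    log2fold_range: tuple[float, float] = (1.0, 2.0)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        need = self.kd_up + self.kd_down + self.atra_extra_up + self.atra_extra_down
        if need > self.n_genes:
            raise ValueError("planted gene sets exceed the gene universe")
        if self.shared_up > self.kd_up or self.shared_down > self.kd_down:
            raise ValueError("shared genes exceed the knockdown lists")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GeneExperiment:
    """One two-condition, two-repeat gene expression experiment."""

    values: pd.DataFrame   # genes x 4 arrays, linear intensities
    samples: pd.DataFrame  # array_id -> condition {ctrl, test}, repeat {1, 2}


def _gene_experiment(rng, genes, baseline, up: set, down: set,
                     folds: dict, noise_sd: float, tag: str) -> GeneExperiment:
    cols, sample_rows = [], []
    mat = np.zeros((len(genes), 4))
    j = 0
    for cond in ("ctrl", "test"):
        for rep in (1, 2):
            arr = f"{tag}_{cond}_{rep}"
            cols.append(arr)
            sample_rows.append({"array_id": arr, "condition": cond, "repeat": rep})
            shift = np.zeros(len(genes))
            if cond == "test":
                for i, g in enumerate(genes):
                    if g in up:
                        shift[i] = folds[g]
                    elif g in down:
                        shift[i] = -folds[g]
            mat[:, j] = baseline + shift + rng.normal(0, noise_sd, len(genes))
            j += 1
    return GeneExperiment(
        values=pd.DataFrame(np.exp2(mat), index=genes, columns=cols),
        samples=pd.DataFrame(sample_rows).set_index("array_id"),
    )


def simulate_gene_dataset(config: GeneSimConfig | None = None,
                          seed: int | None = None
                          ) -> tuple[GeneExperiment, GeneExperiment, pd.DataFrame]:
    """Generate (knockdown experiment, ATRA experiment, truth table)."""
    config = config or GeneSimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    c = config
    kd_up = {genes[i] for i in perm[:c.kd_up]}
    kd_down = {genes[i] for i in perm[c.kd_up:c.kd_up + c.kd_down]}
    extra = perm[c.kd_up + c.kd_down:]
    atra_up = set(sorted(kd_up)[:c.shared_up]) | {genes[i] for i in extra[:c.atra_extra_up]}
    atra_down = set(sorted(kd_down)[:c.shared_down]) | \
        {genes[i] for i in extra[c.atra_extra_up:c.atra_extra_up + c.atra_extra_down]}
    lo, hi = c.log2fold_range
    folds = {g: rng.uniform(lo, hi) for g in sorted(kd_up | kd_down | atra_up | atra_down)}
    baseline = rng.normal(c.baseline_mean, c.baseline_sd, c.n_genes)
    kd = _gene_experiment(rng, genes, baseline, kd_up, kd_down, folds, c.noise_sd, "KD")
    atra = _gene_experiment(rng, genes, baseline, atra_up, atra_down, folds, c.noise_sd, "ATRA")
    truth = pd.DataFrame({
        "gene": genes,
        "kd_label": ["up" if g in kd_up else "down" if g in kd_down else "null"
                     for g in genes],
        "atra_label": ["up" if g in atra_up else "down" if g in atra_down else "null"
                       for g in genes],
    })
    return kd, atra, truth
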