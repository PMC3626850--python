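"""Strand-aware probe tiling design for UCR windows.

Each region is tiled on both genomic strands ("containers") across a window
that extends 2500 bases upstream and 500 bases downstream of the region,
where upstream/downstream follow the host-gene strand for intragenic regions
and the + genomic strand otherwise.  Oligo lengths vary between 50 and 72 nt
so that every probe sits close to a common melting temperature, mimicking
isothermal tiling-array design.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .regions import ExonAnnotation, UCRegion

logger = logging.getLogger(__name__)

FLANK_UPSTREAM = 2500
FLANK_DOWNSTREAM = 500
MIN_PROBE_LEN = 50
MAX_PROBE_LEN = 72
DEFAULT_STEP = 45
DEFAULT_TM_TARGET = 74.0

CONTAINERS = ("plus", "minus")
CONTAINER_STRAND = {"plus": "+", "minus": "-"}

ZONES = ("upstream_flank", "core", "downstream_flank")

PROBE_COLUMNS = ["probe_id", "region", "container", "chrom", "start", "length", "tm", "zone"]

#: GC model: maps (region id, offset within window, probe length) -> GC base count
GCModel = Callable[[str, int, int], float]


def constant_gc(fraction: float = 0.5) -> GCModel:
    """GC model with a uniform GC fraction along every window."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("GC fraction must lie in [0, 1]")

    def model(region_id: str, offset: int, length: int) -> float:
        return fraction * length

    return model


def sequence_gc(sequences: Mapping[str, str]) -> GCModel:
    """GC model reading base counts from per-region window sequences."""

    def model(region_id: str, offset: int, length: int) -> float:
        seq = sequences[region_id][offset:offset + length].upper()
        return seq.count("G") + seq.count("C")

    return model


def melting_temperature(gc_count: float, length: int) -> float:
    """GC-fraction melting temperature: Tm = 64.9 + 41*(G+C - 16.4)/L."""
    return 64.9 + 41.0 * (gc_count - 16.4) / length


def tiled_window(region: UCRegion,
                 flank_up: int = FLANK_UPSTREAM,
                 flank_down: int = FLANK_DOWNSTREAM) -> tuple[int, int]:
    """Genomic window [start, end) tiled for a region.

    Upstream/downstream are taken along the region's orientation strand, so a
    minus-strand host gene puts the long flank on the genomic right.
    Clamped at position 0.
    """
    if region.orientation_strand == "+":
        ws, we = region.start - flank_up, region.end + flank_down
    else:
        ws, we = region.start - flank_down, region.end + flank_up
    return max(ws, 0), we


def _choose_length(gc_model: GCModel, region_id: str, offset: int,
                   tm_target: float) -> tuple[int, float]:
    """Probe length in [50, 72] minimizing |Tm - target|; ties -> shorter."""
    best_len, best_tm, best_diff = MIN_PROBE_LEN, None, math.inf
    for length in range(MIN_PROBE_LEN, MAX_PROBE_LEN + 1):
        tm = melting_temperature(gc_model(region_id, offset, length), length)
        diff = abs(tm - tm_target)
        if diff < best_diff - 1e-12:
            best_len, best_tm, best_diff = length, tm, diff
    return best_len, best_tm


def tile_region(region: UCRegion,
                step: int = DEFAULT_STEP,
                tm_target: float = DEFAULT_TM_TARGET,
                gc_model: GCModel | None = None) -> pd.DataFrame:
    """Tile one region's window on both strand containers at a fixed step.

    Returns a probe table (columns :data:`PROBE_COLUMNS`, zone unset).  Probe
    coordinates are identical between the two containers.  The number of
    probe start positions per container is ``ceil(window/step) + 1``; the
    last starts are clamped so every probe stays inside the window.  A window
    shorter than the minimum probe length yields a single full-window probe.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    gc_model = gc_model or constant_gc()
    ws, we = tiled_window(region)
    window = we - ws
    placements: list[tuple[int, int, float]] = []  # (start, length, tm)
    if window < MIN_PROBE_LEN:
        logger.warning(
            "region %s: window of %d bp is shorter than a %d-mer; emitting one "
            "full-window probe", region.id, window, MIN_PROBE_LEN,
        )
        tm = melting_temperature(gc_model(region.id, 0, window), window)
        placements.append((ws, window, tm))
    else:
        n_pos = math.ceil(window / step) + 1
        for i in range(n_pos):
            offset = min(i * step, window - MIN_PROBE_LEN)
            length, tm = _choose_length(gc_model, region.id, offset, tm_target)
            offset = min(offset, window - length)
            placements.append((ws + offset, length, tm))
    rows = [
        {
            "probe_id": f"{region.id}:{container}:{i:04d}",
            "region": region.id,
            "container": container,
            "chrom": region.chrom,
            "start": start,
            "length": length,
            "tm": tm,
            "zone": None,
        }
        for container in CONTAINERS
        for i, (start, length, tm) in enumerate(placements)
    ]
    return pd.DataFrame(rows, columns=PROBE_COLUMNS)


def assign_zones(probes: pd.DataFrame, regions: Iterable[UCRegion]) -> pd.DataFrame:
    """Assign each probe to the UCR core or a strand-relative flank zone.

    A probe is ``core`` iff its midpoint lies inside the region interval;
    otherwise it is an upstream or downstream flank probe, with the direction
    taken along the region's orientation strand.  Probes outside the tiled
    window raise.
    """
    by_id = {r.id: r for r in regions}
    zones = []
    for rid, start, length in zip(probes["region"], probes["start"], probes["length"]):
        region = by_id[rid]
        ws, we = tiled_window(region)
        if start < ws or start + length > we:
            raise ValueError(
                f"probe at {start} (region {rid}) lies outside the tiled window"
            )
        mid = start + length // 2
        if region.start <= mid < region.end:
            zones.append("core")
        else:
            left = mid < region.start
            if region.orientation_strand == "+":
                zones.append("upstream_flank" if left else "downstream_flank")
            else:
                zones.append("downstream_flank" if left else "upstream_flank")
    out = probes.copy()
    out["zone"] = zones
    return out


def design_probes(regions: Sequence[UCRegion],
                  step: int = DEFAULT_STEP,
                  tm_target: float = DEFAULT_TM_TARGET,
                  gc_model: GCModel | None = None) -> pd.DataFrame:
    """Tile all regions and assign zones; one call covers the whole design."""
    frames = [tile_region(r, step=step, tm_target=tm_target, gc_model=gc_model)
              for r in regions]
    probes = pd.concat(frames, ignore_index=True)
    return assign_zones(probes, regions)


def exon_probe_map(probes: pd.DataFrame,
                   regions: Iterable[UCRegion],
                   exons: Iterable[ExonAnnotation]) -> dict[str, str]:
    """Map probes to host genes via exon overlap on the gene's own strand.

    A probe maps to a gene iff its interval overlaps at least one exon base
    on the same chromosome and the probe's strand container matches the
    gene's transcriptional strand (antisense-container probes over an exon do
    not measure the host mRNA and are excluded).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    genes_seen: set[str] = set()
    for ann in exons:
        genes_seen.add(ann.gene)
        tree = trees.setdefault((ann.chrom, ann.strand), IntervalTree())
        for s, e in ann.exons:
            tree[s:e] = ann.gene

    host_genes = {r.host_gene for r in regions if r.host_gene is not None}
    for gene in sorted(host_genes - genes_seen):
        logger.warning("host gene %s absent from exon annotation; no exon probes", gene)

    mapping: dict[str, str] = {}
    for pid, chrom, container, start, length in zip(
        probes["probe_id"], probes["chrom"], probes["container"],
        probes["start"], probes["length"],
    ):
        tree = trees.get((chrom, CONTAINER_STRAND[container]))
        if tree is None:
            continue
        hits = tree.overlap(start, start + length)
        if hits:
            # a probe window is far smaller than gene spacing; take any hit
            mapping[pid] = sorted(h.data for h in hits)[0]
    return mapping


def write_probes(probes: pd.DataFrame, path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"region": str, "container": str})
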