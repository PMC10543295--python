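"""Founder-pedigree IBD simulator and deterministic test fixtures.

The simulator emulates the statistical structure the clustering method
assumes: a founder carries a rare variant on one haplotype; descendants who
inherit it retain a chromosomal interval around the variant that shrinks
each meiosis as crossovers (Poisson per Haldane's no-interference model)
truncate it on either side.  The pairwise IBD segment shared by two
carriers is exactly the intersection of their retained intervals, emitted
in the hap-IBD dialect together with a carrier truth table.  Background
noise — segments of exponential length between random non-carrier pairs,
uniformly placed — emulates sharing unrelated to the founder event.

``make_cluster_fixture`` builds the deterministic 21-member worked-example
graph (7 "C" clinic samples, 14 "BV" biobank samples) whose connected-pair
percentage rounds to 82.9%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .cluster_stats import round_half_up
from .ibd_io import IBDSegment, TargetLocus, write_ibd

__all__ = [
    "SimConfig",
    "SimResult",
    "crossover_free_interval",
    "transmit_interval",
    "chain_retained_interval",
    "simulate_pedigree_ibd",
    "make_cluster_fixture",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class SimConfig:
    """Founder-pedigree simulation parameters.

    ``generations`` branching-process generations below the founder, with
    Poisson(``offspring_mean``) children per carrier and a 1/2 transmission
    probability per child.  The chromosome is ``chrom_len_cm`` long with a
    uniform map of ``cm_per_mb`` cM per megabase, and the variant sits at
    ``variant_pos_cm``.  ``n_noise_pairs`` exponential-length background
    segments (mean ``noise_mean_cm``) are added between non-carriers.
    """

    generations: int = 6
    offspring_mean: float = 2.5
    chrom_len_cm: float = 150.0
    variant_pos_cm: float = 75.0
    cm_per_mb: float = 1.0
    n_noise_pairs: int = 200
    noise_mean_cm: float = 2.0
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not self.offspring_mean > 0:
            raise ValueError("offspring_mean must be positive")
        if not self.chrom_len_cm > 0:
            raise ValueError("chrom_len_cm must be positive")
        if not 0 < self.variant_pos_cm < self.chrom_len_cm:
            raise ValueError("variant_pos_cm must lie inside (0, chrom_len_cm)")
        if not self.cm_per_mb > 0:
            raise ValueError("cm_per_mb must be positive")
        if self.n_noise_pairs < 0:
            raise ValueError("n_noise_pairs must be >= 0")
        if not self.noise_mean_cm > 0:
            raise ValueError("noise_mean_cm must be positive")

    @property
    def variant_bp(self) -> int:
        return _cm_to_bp(self.variant_pos_cm, self.cm_per_mb)


@dataclass
class SimResult:
    """Simulator output: segments plus the carrier truth table."""

    config: SimConfig
    segments: list[IBDSegment]
    carriers: set[str]
    carrier_hap: dict[str, int]
    retained: dict[str, Interval]  # carrier -> founder-segment interval, cM
    meioses: dict[frozenset, int]  # carrier pair -> meioses separating them

    @property
    def locus(self) -> TargetLocus:
        bp = self.config.variant_bp
        return TargetLocus(self.config.chrom, bp, bp)


def _cm_to_bp(pos_cm: float, cm_per_mb: float) -> int:
    return int(round(pos_cm / cm_per_mb * 1e6)) + 1


def crossover_free_interval(
    variant_pos_cm: float, chrom_len_cm: float, rng: np.random.Generator
) -> Interval:
    """The crossover-free interval around the variant for one meiosis.

    Crossovers are Poisson(chrom_len_cm / 100) with uniform positions
    (Haldane's model: no interference); the interval runs from the nearest
    crossover left of the variant (or 0) to the nearest right of it (or the
    chromosome end).
    """
    k = rng.poisson(chrom_len_cm / 100.0)
    lo, hi = 0.0, chrom_len_cm
    if k:
        xs = rng.uniform(0.0, chrom_len_cm, size=k)
        left = xs[xs < variant_pos_cm]
        right = xs[xs > variant_pos_cm]
        if left.size:
            lo = float(left.max())
        if right.size:
            hi = float(right.min())
    return lo, hi


def transmit_interval(
    interval: Interval,
    variant_pos_cm: float,
    chrom_len_cm: float,
    rng: np.random.Generator,
) -> Interval:
    """Retained interval after one transmitting meiosis: the parent's
    interval intersected with this meiosis's crossover-free interval."""
    lo, hi = crossover_free_interval(variant_pos_cm, chrom_len_cm, rng)
    return max(interval[0], lo), min(interval[1], hi)


def chain_retained_interval(
    n_meioses: int,
    variant_pos_cm: float,
    chrom_len_cm: float,
    rng: np.random.Generator,
) -> Interval:
    """Founder interval after a chain of ``n_meioses`` transmitting meioses
    (conditioning on the allele being passed each time)."""
    interval: Interval = (0.0, chrom_len_cm)
    for _ in range(n_meioses):
        interval = transmit_interval(interval, variant_pos_cm, chrom_len_cm, rng)
    return interval


def simulate_pedigree_ibd(config: SimConfig) -> SimResult:
    """Run the founder-pedigree IBD simulation; fully reproducible from
    ``config.seed``.

    Only the carrier lineage is tracked individual-by-individual (a
    non-carrier can never re-acquire the founder haplotype); non-carriers
    appear solely through the background noise pairs.
    """
    rng = np.random.default_rng(config.seed)
    founder = "F0"
    retained: dict[str, Interval] = {founder: (0.0, config.chrom_len_cm)}
    carrier_hap: dict[str, int] = {founder: 1}
    parent: dict[str, str | None] = {founder: None}
    depth: dict[str, int] = {founder: 0}

    current = [founder]
    counter = 0
    for gen in range(1, config.generations + 1):
        nxt: list[str] = []
        for carrier in current:
            for _ in range(rng.poisson(config.offspring_mean)):
                transmitted = rng.random() < 0.5
                if not transmitted:
                    continue
                counter += 1
                child = f"G{gen}S{counter}"
                retained[child] = transmit_interval(
                    retained[carrier], config.variant_pos_cm, config.chrom_len_cm, rng
                )
                carrier_hap[child] = int(rng.integers(1, 3))
                parent[child] = carrier
                depth[child] = gen
                nxt.append(child)
        current = nxt

    def ancestors(sample: str) -> list[str]:
        chain = [sample]
        while parent[chain[-1]] is not None:
            chain.append(parent[chain[-1]])  # type: ignore[arg-type]
        return chain

    carriers = sorted(retained)
    meioses: dict[frozenset, int] = {}
    segments: list[IBDSegment] = []
    anc = {c: ancestors(c) for c in carriers}
    anc_set = {c: set(a) for c, a in anc.items()}
    for s1, s2 in combinations(carriers, 2):
        lca = next(a for a in anc[s1] if a in anc_set[s2])
        meioses[frozenset((s1, s2))] = (depth[s1] - depth[lca]) + (depth[s2] - depth[lca])
        lo = max(retained[s1][0], retained[s2][0])
        hi = min(retained[s1][1], retained[s2][1])
        start_bp = _cm_to_bp(lo, config.cm_per_mb)
        end_bp = _cm_to_bp(hi, config.cm_per_mb)
        if end_bp <= start_bp:  # interval below bp resolution; unobservable
            continue
        segments.append(
            IBDSegment(
                sample1=s1, hap1=carrier_hap[s1],
                sample2=s2, hap2=carrier_hap[s2],
                chrom=config.chrom,
                start_bp=start_bp, end_bp=end_bp,
                length_cm=hi - lo,
            )
        )

    pool = [f"N{i}" for i in range(1, max(2, config.n_noise_pairs) + 1)]
    for _ in range(config.n_noise_pairs):
        i, j = rng.choice(len(pool), size=2, replace=False)
        s1, s2 = sorted((pool[i], pool[j]))
        length = max(0.01, float(rng.exponential(config.noise_mean_cm)))
        length = min(length, config.chrom_len_cm)
        start_cm = float(rng.uniform(0.0, config.chrom_len_cm - length))
        segments.append(
            IBDSegment(
                sample1=s1, hap1=int(rng.integers(1, 3)),
                sample2=s2, hap2=int(rng.integers(1, 3)),
                chrom=config.chrom,
                start_bp=_cm_to_bp(start_cm, config.cm_per_mb),
                end_bp=_cm_to_bp(start_cm + length, config.cm_per_mb),
                length_cm=length,
            )
        )

    return SimResult(
        config=config,
        segments=segments,
        carriers=set(carriers),
        carrier_hap=carrier_hap,
        retained=retained,
        meioses=meioses,
    )


def write_sim_result(result: SimResult, prefix: str | Path) -> dict[str, Path]:
    """Write simulator output: hap-IBD TSV, carrier truth table, meioses table."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ibd_path = prefix.with_name(prefix.name + ".ibd.tsv")
    write_ibd(result.segments, ibd_path)
    carriers_path = prefix.with_name(prefix.name + ".carriers.tsv")
    with open(carriers_path, "w") as fh:
        fh.write("sample\thap\tretained_lo_cm\tretained_hi_cm\n")
        for sample in sorted(result.carriers):
            lo, hi = result.retained[sample]
            fh.write(f"{sample}\t{result.carrier_hap[sample]}\t{lo:.6f}\t{hi:.6f}\n")
    meioses_path = prefix.with_name(prefix.name + ".meioses.tsv")
    with open(meioses_path, "w") as fh:
        fh.write("sample1\tsample2\tmeioses\n")
        for pair in sorted(result.meioses, key=sorted):
            s1, s2 = sorted(pair)
            fh.write(f"{s1}\t{s2}\t{result.meioses[pair]}\n")
    return {"ibd": ibd_path, "carriers": carriers_path, "meioses": meioses_path}


# --- deterministic worked-example fixture -----------------------------------

_FIXTURE_LOCUS = TargetLocus("21", 35818000, 35884000)


def cluster_a_connected_pairs() -> int:
    """The unique number k of connected pairs among 21 members for which
    100*k/C(21,2) rounds half-up to one decimal as 82.9 — found by scanning
    every k, never assumed."""
    n_pairs = 21 * 20 // 2
    hits = [k for k in range(n_pairs + 1) if round_half_up(100.0 * k / n_pairs, 1) == 82.9]
    if len(hits) != 1:
        raise RuntimeError(f"expected a unique k, found {hits}")
    return hits[0]


def make_cluster_fixture(
    name: str = "clusterA", out_dir: str | Path | None = None
) -> tuple[list[IBDSegment], TargetLocus, dict]:
    """Deterministic 21-node worked-example graph in the hap-IBD dialect.

    Members are C1..C7 and BV1..BV14, haplotype 1 each.  Exactly
    ``cluster_a_connected_pairs()`` of the 210 unordered pairs carry one
    spanning segment longer than 3 cM: the first k pairs in lexicographic
    member order (which keeps the graph connected, since every pair
    involving the first member is included).  Segment lengths sweep
    3.10–19.99 cM by a fixed decorrelating rule, so edge weight carries no
    structure aligned with member order.  When ``out_dir`` is given, the
    segments and the expected summary are written there; regeneration is
    byte-identical.
    """
    if name != "clusterA":
        raise ValueError(f"unknown fixture {name!r}")
    labels = [f"C{i}" for i in range(1, 8)] + [f"BV{i}" for i in range(1, 15)]
    k = cluster_a_connected_pairs()
    pairs = list(combinations(range(len(labels)), 2))[:k]
    locus = _FIXTURE_LOCUS
    mid = (locus.start_bp + locus.end_bp) // 2
    segments = []
    for i, (a, b) in enumerate(pairs):
        length_cm = round(3.1 + ((i * 97) % 1690) / 100.0, 2)
        bp_len = int(round(length_cm * 1e6))
        start = mid - bp_len // 2
        segments.append(
            IBDSegment(
                sample1=labels[a], hap1=1,
                sample2=labels[b], hap2=1,
                chrom=locus.chrom,
                start_bp=start, end_bp=start + bp_len,
                length_cm=length_cm,
            )
        )
    n_pairs = len(labels) * (len(labels) - 1) // 2
    expected = {
        "n_haplotypes": len(labels),
        "n_individuals": len(labels),
        "connected_pairs": k,
        "density_pct": round_half_up(100.0 * k / n_pairs, 1),
        "locus": f"{locus.chrom}:{locus.start_bp}-{locus.end_bp}",
        "min_cm": 3.0,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ibd(segments, out_dir / f"{name}.ibd.tsv")
        with open(out_dir / f"{name}.expected.json", "w") as fh:
            json.dump(expected, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return segments, locus, expected
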