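"""Seeded synthetic-genome simulator.

Produces a toy genome with planted replication-timing (RT) domains,
Rif1-style and lamin-style occupancy domains, sequence features (CpG
islands, G4 motifs, G-rich elements), binned sequencing assays and
two-genotype 4C-style fragment libraries — together with a full record of
the planted truth, so every downstream analysis stage can be validated by
parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import BinnedTrack, GenomicInterval, IntervalSet

__all__ = [
    "SyntheticGenomeSpec",
    "PlantedTruth",
    "Viewpoint",
    "SimulatedAssays",
    "FourCLibraries",
    "simulate_genome",
    "simulate_replication_assays",
    "simulate_4c_libraries",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeSpec:
    """Full parameterization of the simulated genome, assays and planted truth.

    All coordinates in bp. RT domains alternate early/late blocks of
    ``rt_block_bp``; every late block hosts a Rif1-occupied domain (RAD) and
    a configurable fraction of RADs is co-occupied by a lamin domain (LAD).
    The knockout RT layout flips lamin-free RADs to early and a configurable
    subset of early blocks to late.
    """

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    bin_size: int = 50_000
    # RT layout
    rt_block_bp: int = 2_000_000
    rt_early_mean: float = 2.0
    rt_late_mean: float = -2.0
    # occupancy-domain layout
    rad_fraction_of_late: float = 0.8
    frac_rads_lb_plus: float = 0.5
    lad_coverage_lb_plus: float = 1.0
    lad_coverage_lb_minus: float = 0.0
    n_extra_lads_per_chrom: int = 2
    extra_lad_bp: int = 600_000
    # knockout RT rewiring
    early_flip_fraction: float = 0.2
    # assay depth / effects
    depth: float = 100.0
    chip_effect: float = 1.5
    lamin_effect: float = 1.5
    tss_peak_effect: float = 2.0
    # sequence composition
    gc_background: float = 0.4
    n_tss_per_chrom: int = 40
    cpg_island_fraction: float = 0.5
    cpg_island_bp: int = 1_000
    n_sns_per_chrom: int = 60
    n_g4_per_chrom: int = 20
    g4_motif: str = "GGGAGGGTGGGAGGG"
    n_ogre_per_chrom: int = 10
    ogre_bp: int = 40
    # 4C parameters
    n_viewpoints: int = 6
    restriction_motif: str = "AAGCTT"
    decay_exponent: float = 2.0
    decay_floor_bp: int = 10_000
    same_rt_preference: float = 3.0
    trans_weight: float = 0.005
    vp_zone_bp: int = 10_000
    vp_read_fraction: float = 0.5
    reads_per_library: int = 1_000_000
    n_replicates: int = 2
    n_true_contacts: int = 80
    true_contact_rpm: Tuple[float, float] = (30.0, 300.0)
    target_block_fraction: float = 0.4
    min_contact_dist_bp: int = 3_000_000
    n_intra_contacts: int = 15
    intra_boost: float = 6.0
    gained_rate: float = 0.02
    gained_rpm: Tuple[float, float] = (15.0, 100.0)
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming the offending field on invalid parameters."""
        positive = [
            "bin_size", "rt_block_bp", "depth", "cpg_island_bp", "ogre_bp",
            "decay_floor_bp", "vp_zone_bp", "reads_per_library",
            "n_replicates", "min_contact_dist_bp", "intra_boost",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        fractions = [
            "rad_fraction_of_late", "frac_rads_lb_plus", "lad_coverage_lb_plus",
            "lad_coverage_lb_minus", "early_flip_fraction", "gc_background",
            "cpg_island_fraction", "target_block_fraction", "vp_read_fraction",
            "trans_weight", "gained_rate",
        ]
        for name in fractions:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chrom_lengths[{name!r}] must be strictly positive")
            if self.rt_block_bp > length:
                raise ValueError("rt_block_bp exceeds chromosome length")
        if self.rt_early_mean <= self.rt_late_mean:
            raise ValueError("rt_early_mean must exceed rt_late_mean")
        if len(self.restriction_motif) < 4:
            raise ValueError("restriction_motif must be at least 4 bp")
        for name in ("true_contact_rpm", "gained_rpm"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be an increasing positive range")


@dataclass
class Viewpoint:
    name: str
    chrom: str
    pos: int
    rt_domain: GenomicInterval
    rt_class: int  # +1 early, -1 late


@dataclass
class PlantedTruth:
    """Ground truth planted by the simulator, for parameter-recovery tests."""

    rt_class: Dict[str, np.ndarray]          # per bin: +1 early, -1 late
    rt_wt: Dict[str, np.ndarray]             # per-bin planted RT, wild type
    rt_ko: Dict[str, np.ndarray]             # per-bin planted RT, knockout
    rt_domains: List[Tuple[GenomicInterval, str]]   # ("early"|"late") blocks
    rads: IntervalSet
    lads: IntervalSet
    rads_lb_plus: IntervalSet
    rads_lb_minus: IntervalSet
    switch_classes: List[Tuple[GenomicInterval, str]]  # EtoE/EtoL/LtoE/LtoL
    tss: List[Tuple[str, int, bool]]         # (chrom, pos, is_cpg_island)
    sns: List[Tuple[str, int]]
    g4_intervals: IntervalSet
    ogre_intervals: IntervalSet
    viewpoints: List[Viewpoint]
    # filled by simulate_4c_libraries
    true_contacts: Dict[str, List[Tuple[int, float]]] = field(default_factory=dict)
    intra_contacts: Dict[str, List[int]] = field(default_factory=dict)
    gained_contacts: Dict[str, List[Tuple[int, float]]] = field(default_factory=dict)

    def rt_domain_of(self, chrom: str, pos: int) -> Optional[GenomicInterval]:
        for iv, _cls in self.rt_domains:
            if iv.contains_point(chrom, pos):
                return iv
        return None


@dataclass
class SimulatedAssays:
    """Binned count tracks for both genotypes plus ChIP/input per factor."""

    early: Dict[str, Dict[str, BinnedTrack]]   # genotype -> chrom -> track
    late: Dict[str, Dict[str, BinnedTrack]]
    chip: Dict[str, Dict[str, BinnedTrack]]    # factor -> chrom -> track
    chip_input: Dict[str, BinnedTrack]


@dataclass
class FourCLibraries:
    """Per-fragment 4C read counts keyed by (viewpoint, genotype, replicate)."""

    fragment_map: "FragmentMap"
    counts: Dict[Tuple[str, str, int], Dict[str, np.ndarray]]
    expected: Dict[Tuple[str, str], Dict[str, np.ndarray]]


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _rt_blocks(spec: SyntheticGenomeSpec) -> List[Tuple[GenomicInterval, str]]:
    blocks: List[Tuple[GenomicInterval, str]] = []
    for chrom, length in spec.chrom_lengths.items():
        pos, early = 0, True
        while pos < length:
            end = min(pos + spec.rt_block_bp, length)
            blocks.append((GenomicInterval(chrom, pos, end), "early" if early else "late"))
            pos, early = end, not early
    return blocks


def simulate_genome(spec: SyntheticGenomeSpec) -> Tuple[Dict[str, str], PlantedTruth]:
    """Generate chromosome sequences and the planted-truth record.

    Deterministic for a fixed ``spec.seed``: two calls with the same spec
    return byte-identical sequences and identical truth.
    """
    spec.validate()
    rng = _child_rng(spec.seed, 0)

    blocks = _rt_blocks(spec)

    # --- occupancy domains ------------------------------------------------
    late_blocks = [iv for iv, cls in blocks if cls == "late"]
    n_rads = int(round(spec.rad_fraction_of_late * len(late_blocks)))
    rad_pick = sorted(rng.choice(len(late_blocks), size=n_rads, replace=False))
    rads = [late_blocks[i] for i in rad_pick]

    n_plus = int(round(spec.frac_rads_lb_plus * len(rads)))
    plus_pick = set(rng.choice(len(rads), size=n_plus, replace=False).tolist())
    rads_plus = [r for i, r in enumerate(rads) if i in plus_pick]
    rads_minus = [r for i, r in enumerate(rads) if i not in plus_pick]

    lads: List[GenomicInterval] = []
    for r, frac in [(r, spec.lad_coverage_lb_plus) for r in rads_plus] + [
        (r, spec.lad_coverage_lb_minus) for r in rads_minus
    ]:
        w = int(round(frac * r.length))
        if w > 0:
            s = r.mid - w // 2
            lads.append(GenomicInterval(r.chrom, max(r.start, s), min(r.end, s + w)))
    # standalone lamin domains inside early blocks ("lamin-only" regions)
    early_blocks = [iv for iv, cls in blocks if cls == "early"]
    by_chrom_early: Dict[str, List[GenomicInterval]] = {}
    for iv in early_blocks:
        by_chrom_early.setdefault(iv.chrom, []).append(iv)
    for chrom in spec.chrom_lengths:
        host_pool = by_chrom_early.get(chrom, [])
        n_extra = min(spec.n_extra_lads_per_chrom, len(host_pool))
        if n_extra == 0:
            continue
        hosts = rng.choice(len(host_pool), size=n_extra, replace=False)
        for hi in sorted(hosts):
            host = host_pool[hi]
            w = min(spec.extra_lad_bp, host.length)
            s = host.mid - w // 2
            lads.append(GenomicInterval(chrom, max(host.start, s), s + w))

    # --- RT layouts and switch classes ------------------------------------
    rt_class: Dict[str, np.ndarray] = {}
    rt_wt: Dict[str, np.ndarray] = {}
    rt_ko: Dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        n_bins = int(np.ceil(length / spec.bin_size))
        rt_class[chrom] = np.zeros(n_bins, dtype=int)
        rt_wt[chrom] = np.zeros(n_bins)
        rt_ko[chrom] = np.zeros(n_bins)

    minus_set = IntervalSet(rads_minus)
    n_early = len(early_blocks)
    n_flip = int(round(spec.early_flip_fraction * n_early))
    flip_pick = set(rng.choice(n_early, size=n_flip, replace=False).tolist()) if n_flip else set()

    switch_classes: List[Tuple[GenomicInterval, str]] = []
    early_idx = 0
    for iv, cls in blocks:
        b0 = iv.start // spec.bin_size
        b1 = int(np.ceil(iv.end / spec.bin_size))
        # triangular within-domain taper: 0.75x at the edges, 1.25x at the
        # centre, domain mean exactly 1x — gives RT values within-class
        # spread so medians of mixed contact sets interpolate sensibly
        u = (np.arange(b1 - b0) + 0.5) / (b1 - b0)
        shape = 0.75 + 0.5 * (1.0 - np.abs(2.0 * u - 1.0))
        if cls == "early":
            rt_class[iv.chrom][b0:b1] = 1
            rt_wt[iv.chrom][b0:b1] = spec.rt_early_mean * shape
            if early_idx in flip_pick:
                rt_ko[iv.chrom][b0:b1] = spec.rt_late_mean * shape
                switch_classes.append((iv, "EtoL"))
            else:
                rt_ko[iv.chrom][b0:b1] = spec.rt_early_mean * shape
                switch_classes.append((iv, "EtoE"))
            early_idx += 1
        else:
            rt_class[iv.chrom][b0:b1] = -1
            rt_wt[iv.chrom][b0:b1] = spec.rt_late_mean * shape
            # lamin-free RADs switch late -> early in the knockout
            if minus_set.coverage_bp_of(iv) > iv.length // 2:
                rt_ko[iv.chrom][b0:b1] = spec.rt_early_mean * shape
                switch_classes.append((iv, "LtoE"))
            else:
                rt_ko[iv.chrom][b0:b1] = spec.rt_late_mean * shape
                switch_classes.append((iv, "LtoL"))

    # --- sequence ----------------------------------------------------------
    gc = spec.gc_background
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    cum = np.cumsum(probs)
    seqs: Dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        draws = rng.random(length)
        codes = (
            (draws > cum[0]).astype(np.uint8)
            + (draws > cum[1])
            + (draws > cum[2])
        )
        seqs[chrom] = _BASES[codes]

    # TSSs (half in early, half in late blocks), CpG islands at a subset
    tss: List[Tuple[str, int, bool]] = []
    sns: List[Tuple[str, int]] = []
    for chrom, length in spec.chrom_lengths.items():
        ch_blocks = [(iv, cls) for iv, cls in blocks if iv.chrom == chrom]
        early_ivs = [iv for iv, cls in ch_blocks if cls == "early"]
        late_ivs = [iv for iv, cls in ch_blocks if cls == "late"]

        def _sample_positions(n: int, pool: List[GenomicInterval], pad: int) -> List[int]:
            pos = []
            for _ in range(n):
                host = pool[int(rng.integers(len(pool)))]
                lo, hi = host.start + pad, host.end - pad
                pos.append(int(rng.integers(lo, hi)))
            return pos

        pad = spec.cpg_island_bp + 100
        n_half = spec.n_tss_per_chrom // 2
        tss_pos = _sample_positions(n_half, early_ivs, pad) + _sample_positions(
            spec.n_tss_per_chrom - n_half, late_ivs, pad
        )
        island_flags = rng.random(spec.n_tss_per_chrom) < spec.cpg_island_fraction
        for p, isl in zip(tss_pos, island_flags):
            tss.append((chrom, p, bool(isl)))
        n_half = spec.n_sns_per_chrom // 2
        for p in _sample_positions(n_half, early_ivs, 1000) + _sample_positions(
            spec.n_sns_per_chrom - n_half, late_ivs, 1000
        ):
            sns.append((chrom, p))

    # plant CpG islands centred at island TSSs: CG-dinucleotide-rich sequence
    for chrom, pos, isl in tss:
        if not isl:
            continue
        w = spec.cpg_island_bp
        s = pos - w // 2
        island = _cpg_island_sequence(rng, w)
        seqs[chrom][s : s + w] = island

    # plant G4 motifs and G-rich elements at recorded coordinates
    g4_hits: List[GenomicInterval] = []
    ogre_hits: List[GenomicInterval] = []
    motif = np.frombuffer(spec.g4_motif.encode(), dtype=np.uint8)
    for chrom, length in spec.chrom_lengths.items():
        for _ in range(spec.n_g4_per_chrom):
            p = int(rng.integers(1000, length - 1000))
            seqs[chrom][p : p + len(motif)] = motif
            g4_hits.append(GenomicInterval(chrom, p, p + len(motif)))
        for _ in range(spec.n_ogre_per_chrom):
            p = int(rng.integers(1000, length - 1000))
            seqs[chrom][p : p + spec.ogre_bp] = ord("G")
            ogre_hits.append(GenomicInterval(chrom, p, p + spec.ogre_bp))

    sequences = {c: a.tobytes().decode("ascii") for c, a in seqs.items()}

    # --- viewpoints: block centres, alternating late/early -----------------
    viewpoints: List[Viewpoint] = []
    eligible: List[Tuple[GenomicInterval, str]] = [
        (iv, cls)
        for iv, cls in blocks
        if iv.start >= spec.rt_block_bp and iv.end <= spec.chrom_lengths[iv.chrom] - spec.rt_block_bp
    ]
    late_pool = [iv for iv, cls in eligible if cls == "late"]
    early_pool = [iv for iv, cls in eligible if cls == "early"]
    for i in range(spec.n_viewpoints):
        pool = late_pool if i % 2 == 0 else early_pool
        host = pool[(i // 2) * 3 % len(pool)]
        cls = -1 if i % 2 == 0 else 1
        viewpoints.append(
            Viewpoint(f"VP{i + 1}", host.chrom, host.mid, host, cls)
        )

    truth = PlantedTruth(
        rt_class=rt_class,
        rt_wt=rt_wt,
        rt_ko=rt_ko,
        rt_domains=blocks,
        rads=IntervalSet(rads),
        lads=IntervalSet(lads).merge(),
        rads_lb_plus=IntervalSet(rads_plus),
        rads_lb_minus=IntervalSet(rads_minus),
        switch_classes=switch_classes,
        tss=tss,
        sns=sns,
        g4_intervals=IntervalSet(g4_hits),
        ogre_intervals=IntervalSet(ogre_hits),
        viewpoints=viewpoints,
    )
    return sequences, truth


def _cpg_island_sequence(rng: np.random.Generator, width: int) -> np.ndarray:
    """CG-dinucleotide-dense sequence of the requested width."""
    out = np.empty(width, dtype=np.uint8)
    i = 0
    while i < width:
        if rng.random() < 0.6 and i + 1 < width:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            out[i] = _BASES[int(rng.integers(1, 3))]  # C or G
            i += 1
    return out


def simulate_replication_assays(
    spec: SyntheticGenomeSpec, truth: PlantedTruth
) -> SimulatedAssays:
    """Draw Poisson count tracks for Repli-seq and ChIP assays.

    Early/late rates are split so the expected log2(early/late) of a bin
    equals its planted RT; ChIP rates multiply the input depth by
    2**effect inside occupied domains.
    """
    spec.validate()
    rng = _child_rng(spec.seed, 1)

    def _domain_bins(chrom: str, n_bins: int, ivs: IntervalSet) -> np.ndarray:
        inside = np.zeros(n_bins, dtype=bool)
        for iv in ivs:
            if iv.chrom == chrom:
                b0 = iv.start // spec.bin_size
                b1 = int(np.ceil(iv.end / spec.bin_size))
                inside[b0:b1] = True
        return inside

    early: Dict[str, Dict[str, BinnedTrack]] = {"wt": {}, "ko": {}}
    late: Dict[str, Dict[str, BinnedTrack]] = {"wt": {}, "ko": {}}
    chip: Dict[str, Dict[str, BinnedTrack]] = {"rif1": {}, "laminB1": {}}
    chip_input: Dict[str, BinnedTrack] = {}

    cpg_tss_bins: Dict[str, set] = {}
    for chrom, pos, isl in truth.tss:
        if isl:
            cpg_tss_bins.setdefault(chrom, set()).add(pos // spec.bin_size)

    for chrom in spec.chrom_lengths:
        n_bins = len(truth.rt_wt[chrom])
        for genotype, rt in (("wt", truth.rt_wt), ("ko", truth.rt_ko)):
            lam_e = spec.depth * np.exp2(rt[chrom] / 2.0)
            lam_l = spec.depth * np.exp2(-rt[chrom] / 2.0)
            early[genotype][chrom] = BinnedTrack(
                chrom, spec.bin_size, rng.poisson(lam_e).astype(float)
            )
            late[genotype][chrom] = BinnedTrack(
                chrom, spec.bin_size, rng.poisson(lam_l).astype(float)
            )
        in_rad = _domain_bins(chrom, n_bins, truth.rads)
        in_lad = _domain_bins(chrom, n_bins, truth.lads)
        eff = spec.chip_effect * in_rad.astype(float)
        for b in cpg_tss_bins.get(chrom, ()):
            eff[b] += spec.tss_peak_effect
        chip["rif1"][chrom] = BinnedTrack(
            chrom, spec.bin_size, rng.poisson(spec.depth * np.exp2(eff)).astype(float)
        )
        chip["laminB1"][chrom] = BinnedTrack(
            chrom,
            spec.bin_size,
            rng.poisson(spec.depth * np.exp2(spec.lamin_effect * in_lad)).astype(float),
        )
        chip_input[chrom] = BinnedTrack(
            chrom, spec.bin_size, rng.poisson(spec.depth, size=n_bins).astype(float)
        )

    return SimulatedAssays(early=early, late=late, chip=chip, chip_input=chip_input)


def simulate_4c_libraries(
    spec: SyntheticGenomeSpec,
    truth: PlantedTruth,
    sequences: Dict[str, str],
) -> FourCLibraries:
    """Simulate per-viewpoint, per-genotype, per-replicate 4C count tables.

    Fragments come from in-silico digestion at ``spec.restriction_motif``.
    Cis reads follow a power-law distance decay multiplied by a same-RT
    compartment preference; a fixed budget lands in the viewpoint zone and a
    small share goes trans. True contacts (both genotypes) are planted in a
    biased subset of same-RT blocks; knockout libraries additionally gain
    contacts at random inter-domain fragments in the configured RPM range.
    Replicates share expected counts and differ only by Poisson noise.

    Fills ``truth.true_contacts``, ``truth.intra_contacts`` and
    ``truth.gained_contacts`` (fragment indices on the viewpoint chromosome).
    """
    from .contacts import digest  # local import to avoid a cycle

    spec.validate()
    rng = _child_rng(spec.seed, 2)
    fragmap = digest(sequences, motif=spec.restriction_motif)

    expected: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    counts: Dict[Tuple[str, str, int], Dict[str, np.ndarray]] = {}

    R = spec.reads_per_library * (1.0 - spec.vp_read_fraction)

    for vp in truth.viewpoints:
        frags = fragmap.fragments[vp.chrom]
        mids = (frags[:, 0] + frags[:, 1]) // 2
        d = np.abs(mids - vp.pos).astype(float)
        in_zone = d <= spec.vp_zone_bp
        if not in_zone.any():
            raise ValueError(f"viewpoint {vp.name} not on any fragment")

        n_bins_track = len(truth.rt_class[vp.chrom])
        frag_cls = truth.rt_class[vp.chrom][
            np.minimum(mids // spec.bin_size, n_bins_track - 1)
        ]
        in_domain = (mids >= vp.rt_domain.start) & (mids < vp.rt_domain.end)
        far = d >= spec.min_contact_dist_bp

        # --- planted true contacts in a biased subset of distal blocks ----
        blocks_here = [
            (iv, cls)
            for iv, cls in truth.rt_domains
            if iv.chrom == vp.chrom
            and abs(iv.mid - vp.pos) >= spec.min_contact_dist_bp
        ]
        n_target = max(1, int(round(spec.target_block_fraction * len(blocks_here))))
        w_block = np.array(
            [
                spec.same_rt_preference
                if (cls == "late") == (vp.rt_class == -1)
                else 1.0
                for _, cls in blocks_here
            ]
        )
        order = np.argsort(-(w_block + rng.random(len(blocks_here)) * 0.5))
        target_blocks = [blocks_here[i] for i in order[:n_target]]
        target_mask = np.zeros(len(mids), dtype=bool)
        for iv, _cls in target_blocks:
            target_mask |= (mids >= iv.start) & (mids < iv.end)
        cand = np.flatnonzero(target_mask & far & ~in_zone)
        n_true = min(spec.n_true_contacts, len(cand))
        true_idx = np.sort(rng.choice(cand, size=n_true, replace=False))
        true_rpm = rng.uniform(*spec.true_contact_rpm, size=n_true)
        truth.true_contacts[vp.name] = list(zip(true_idx.tolist(), true_rpm.tolist()))

        # --- intra-domain contacts: fixed boost over the decay background -
        intra_cand = np.flatnonzero(
            in_domain & ~in_zone & (d >= 200_000) & ~np.isin(np.arange(len(mids)), true_idx)
        )
        n_intra = min(spec.n_intra_contacts, len(intra_cand))
        intra_idx = np.sort(rng.choice(intra_cand, size=n_intra, replace=False))
        truth.intra_contacts[vp.name] = intra_idx.tolist()

        # --- knockout gained contacts: random inter-domain fragments ------
        # stratified across RT classes so gains carry no RT specificity, and
        # restricted to blocks the viewpoint does not already contact so
        # they represent genuinely new interactions
        gain_eligible = (
            ~in_domain
            & ~target_mask
            & far
            & ~in_zone
            & ~np.isin(np.arange(len(mids)), np.concatenate([true_idx, intra_idx]))
        )
        n_gain_total = int(round(spec.gained_rate * int(gain_eligible.sum())))
        picks: List[np.ndarray] = []
        for cls_val in (-1, 1):
            pool = np.flatnonzero(gain_eligible & (frag_cls == cls_val))
            n_pick = min(n_gain_total // 2, len(pool))
            if n_pick:
                picks.append(rng.choice(pool, size=n_pick, replace=False))
        gained_idx = np.sort(np.concatenate(picks)) if picks else np.empty(0, dtype=int)
        gained_rpm = rng.uniform(*spec.gained_rpm, size=len(gained_idx))
        truth.gained_contacts[vp.name] = list(
            zip(gained_idx.tolist(), gained_rpm.tolist())
        )

        # --- expected count composition ----------------------------------
        pref = np.where(frag_cls == vp.rt_class, spec.same_rt_preference, 1.0)
        w_decay = (d + spec.decay_floor_bp) ** (-spec.decay_exponent) * pref

        t_true = true_rpm.sum() * R / 1e6
        t_gain = gained_rpm.sum() * R / 1e6
        t_trans = spec.trans_weight * R

        bg_mask = ~in_zone.copy()
        bg_mask[true_idx] = False
        bg_mask[gained_idx] = False
        w_bg = np.where(bg_mask, w_decay, 0.0)
        w_bg_norm = w_bg / w_bg.sum()
        s_intra = w_bg_norm[intra_idx].sum()

        for genotype in ("wt", "ko"):
            planted = t_true + (t_gain if genotype == "ko" else 0.0)
            bg_budget = (R - planted - t_trans) / (
                1.0 + (spec.intra_boost - 1.0) * s_intra
            )
            e_cis = bg_budget * w_bg_norm
            e_cis[intra_idx] *= spec.intra_boost
            e_cis[true_idx] = true_rpm * R / 1e6
            if genotype == "ko":
                e_cis[gained_idx] = gained_rpm * R / 1e6
            # viewpoint zone gets its fixed share, decay-distributed
            w_zone = np.where(in_zone, w_decay, 0.0)
            e_cis = e_cis + spec.reads_per_library * spec.vp_read_fraction * (
                w_zone / w_zone.sum()
            )
            exp: Dict[str, np.ndarray] = {vp.chrom: e_cis}
            trans_chroms = [c for c in fragmap.fragments if c != vp.chrom]
            n_trans = sum(len(fragmap.fragments[c]) for c in trans_chroms)
            for c in trans_chroms:
                exp[c] = np.full(len(fragmap.fragments[c]), t_trans / max(n_trans, 1))
            expected[(vp.name, genotype)] = exp
            for rep in range(1, spec.n_replicates + 1):
                counts[(vp.name, genotype, rep)] = {
                    c: rng.poisson(e).astype(float) for c, e in exp.items()
                }

    return FourCLibraries(fragment_map=fragmap, counts=counts, expected=expected)
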