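"""Ground-truthed synthetic SAG generator.

Emulates the statistical structure single-cell genomics pipelines assume:
multiple bacterial strains per host at controlled divergence, MDA
amplification bias (lognormal per-window depth), locus dropout (which
defines true completeness), sequencing errors, chimeric reads joining
non-contiguous loci, cross-species contamination, and host-genome
contamination. Every emitted read carries truth in a manifest so recall and
false-positive rates of downstream cleaning are exactly measurable.

Assemblies are produced by truncating the true genome at dropout windows,
not by assembling the simulated reads: true completeness is then exactly
known and no external assembler is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import (
    ConfigurationError,
    Contig,
    GenomeAssembly,
    Read,
    ReadSet,
    revcomp,
    write_fasta,
    write_fastq,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

MARKER_LENGTH = 900
DROPOUT_WINDOW = 5000
MAX_MARKER_OCCUPANCY = 0.6


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a skin-bacterium single-cell sequencing experiment:
    100 kb genomes (a desk-scale stand-in for Mb-scale bacterial genomes),
    150 bp reads as in 2x150 bp Illumina runs, strain divergence spanning
    the within-species band, MDA-like lognormal coverage skew, and low but
    non-zero chimera/contamination rates.
    """

    genome_length: int = 100_000
    gc_content: float = 0.5
    n_strains: int = 3
    between_strain_ani: float = 0.97
    within_strain_ani: float = 0.999
    target_ani_matrix: list[list[float]] | None = None
    sags_per_strain: int = 3
    target_completeness: float = 0.8
    completeness_range: tuple[float, float] | None = None  # per-SAG U(lo, hi)
    read_length: int = 150
    mean_depth: float = 10.0
    lognormal_sigma: float = 0.8
    error_rate: float = 0.005
    chimera_rate: float = 0.05
    contam_rate: float = 0.0
    host_decoy_rate: float = 0.0
    degraded_read_fraction: float = 0.0
    n_markers: int | None = None
    marker_length: int = MARKER_LENGTH
    dropout_window: int = DROPOUT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ConfigurationError("genome_length must be >= 10,000 bp")
        if self.read_length < 50:
            raise ConfigurationError("read_length must be >= 50 bp")
        for name in (
            "gc_content",
            "target_completeness",
            "error_rate",
            "chimera_rate",
            "contam_rate",
            "host_decoy_rate",
            "degraded_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.90 <= self.between_strain_ani <= 1.0:
            raise ConfigurationError("between_strain_ani must be in [0.90, 1.0]")
        if not 0.90 <= self.within_strain_ani <= 1.0:
            raise ConfigurationError("within_strain_ani must be in [0.90, 1.0]")
        if self.completeness_range is not None:
            lo, hi = self.completeness_range
            if not 0.0 <= lo <= hi <= 1.0:
                raise ConfigurationError("completeness_range must be 0 <= lo <= hi <= 1")
        if self.target_ani_matrix is not None:
            m = np.asarray(self.target_ani_matrix, dtype=float)
            if m.shape != (self.n_strains, self.n_strains):
                raise ConfigurationError("target_ani_matrix shape must be n_strains^2")
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
                raise ConfigurationError(
                    "target_ani_matrix must be symmetric with unit diagonal"
                )

    def resolved_n_markers(self) -> int:
        cap = int(MAX_MARKER_OCCUPANCY * self.genome_length / self.marker_length)
        if self.n_markers is None:
            return min(100, cap)
        if self.n_markers > cap:
            raise ConfigurationError(
                f"{self.n_markers} markers of {self.marker_length} bp exceed "
                f"{MAX_MARKER_OCCUPANCY:.0%} of a {self.genome_length} bp genome"
            )
        return self.n_markers


@dataclass
class ManifestRow:
    read_id: str
    sag_id: str
    strain_id: str
    origin_contig: str
    origin_start: int
    origin_end: int
    is_chimeric: bool
    junction_pos: int | None
    is_contaminant: bool
    is_host: bool


@dataclass
class TruthManifest:
    """Per-read and per-SAG ground truth for a simulated cohort."""

    rows: list[ManifestRow] = field(default_factory=list)
    sag_strain: dict[str, str] = field(default_factory=dict)
    dropped_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    true_completeness: dict[str, float] = field(default_factory=dict)

    def extend(self, other: "TruthManifest") -> None:
        self.rows.extend(other.rows)
        self.sag_strain.update(other.sag_strain)
        self.dropped_intervals.update(other.dropped_intervals)
        self.true_completeness.update(other.true_completeness)

    def by_read(self) -> dict[str, ManifestRow]:
        return {r.read_id: r for r in self.rows}

    def to_tsv(self, path: str | Path) -> None:
        cols = (
            "read_id\tsag_id\tstrain_id\torigin_contig\torigin_start\torigin_end"
            "\tis_chimeric\tjunction_pos\tis_contaminant\tis_host\n"
        )
        with open(path, "w") as fh:
            fh.write(cols)
            for r in self.rows:
                fh.write(
                    f"{r.read_id}\t{r.sag_id}\t{r.strain_id}\t{r.origin_contig}\t"
                    f"{r.origin_start}\t{r.origin_end}\t{int(r.is_chimeric)}\t"
                    f"{'' if r.junction_pos is None else r.junction_pos}\t"
                    f"{int(r.is_contaminant)}\t{int(r.is_host)}\n"
                )


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_ancestor(length: int, gc: float, seed: int) -> GenomeAssembly:
    """Random ancestor genome: i.i.d. bases with expected G+C fraction ``gc``."""
    if length < 10_000:
        raise ConfigurationError("ancestor length must be >= 10,000 bp")
    if not 0.0 <= gc <= 1.0:
        raise ConfigurationError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    seq = _BASES[idx].tobytes().decode()
    return GenomeAssembly("ancestor", [Contig("ancestor_c0", seq)], source="reference")


def mutate_to_ani(
    base: GenomeAssembly, target_identity: float, seed: int, derived_id: str | None = None
) -> GenomeAssembly:
    """Derive a genome by uniform per-site substitution at rate 1 - target_identity.

    No indels: alignment-free (Hamming) site identity to ``base`` equals the
    target within binomial error.
    """
    if not 0.90 <= target_identity <= 1.0:
        raise ConfigurationError("target_identity must be in [0.90, 1.0]")
    rng = np.random.default_rng(seed)
    rate = 1.0 - target_identity
    contigs = []
    for c in base.contigs:
        arr = np.frombuffer(c.seq.encode(), dtype="S1").copy()
        if rate > 0:
            hit = np.nonzero(rng.random(len(arr)) < rate)[0]
            if hit.size:
                orig = np.array([_BASE_INDEX[b.decode()] for b in arr[hit]])
                arr[hit] = _BASES[(orig + rng.integers(1, 4, size=hit.size)) % 4]
        contigs.append(Contig(c.contig_id, arr.tobytes().decode()))
    return GenomeAssembly(derived_id or base.sag_id, contigs, source=base.source)


def plant_markers(
    ancestor: GenomeAssembly, n_markers: int, marker_length: int, seed: int
) -> tuple[GenomeAssembly, list[tuple[int, int]]]:
    """Choose ``n_markers`` non-overlapping loci on the (single-contig)
    ancestor and record their sequences as the single-copy marker set.

    Loci are placed by drawing the inter-marker gaps from a symmetric
    multinomial, so placement is uniform over valid non-overlapping layouts
    and never stalls at high occupancy.
    """
    seq = ancestor.contigs[0].seq
    free = len(seq) - n_markers * marker_length
    if free < 0:
        raise ConfigurationError("markers do not fit in the ancestor genome")
    rng = np.random.default_rng(seed)
    gaps = rng.multinomial(free, [1.0 / (n_markers + 1)] * (n_markers + 1))
    loci = []
    pos = 0
    for i in range(n_markers):
        pos += int(gaps[i])
        loci.append((pos, pos + marker_length))
        pos += marker_length
    contigs = [
        Contig(f"marker_{i:03d}", seq[s:e]) for i, (s, e) in enumerate(loci)
    ]
    return GenomeAssembly("markers", contigs, source="reference"), loci


def divergences_from_ani_matrix(matrix: np.ndarray) -> np.ndarray:
    """Per-strain divergence from the ancestor under a star phylogeny.

    Pairwise identity between strains i and j with per-site divergences
    p_i, p_j from the common ancestor is ~ 1 - p_i - p_j (independent
    sites, coincident identical substitutions negligible), so the p_i are
    the least-squares solution of p_i + p_j = 1 - ani_ij over all pairs.
    """
    n = matrix.shape[0]
    rows, rhs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(n)
            row[i] = row[j] = 1.0
            rows.append(row)
            rhs.append(1.0 - matrix[i, j])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return np.clip(sol, 0.0, None)


def simulate_strains(cfg: SimulationConfig, ancestor: GenomeAssembly) -> list[GenomeAssembly]:
    """Derive ``cfg.n_strains`` strain genomes from the ancestor at the
    configured pairwise divergence (star phylogeny)."""
    if cfg.target_ani_matrix is not None:
        p = divergences_from_ani_matrix(np.asarray(cfg.target_ani_matrix, dtype=float))
    else:
        p = np.full(cfg.n_strains, (1.0 - cfg.between_strain_ani) / 2.0)
    seeds = _child_seeds(cfg.seed + 1, cfg.n_strains)
    return [
        mutate_to_ani(ancestor, 1.0 - float(p[i]), seeds[i], derived_id=f"strain_{i}")
        for i in range(cfg.n_strains)
    ]


def auxiliary_genomes(cfg: SimulationConfig) -> tuple[GenomeAssembly, GenomeAssembly]:
    """Deterministic contaminant species and host decoy genomes for a config.

    The contaminant is an unrelated random genome at shifted GC (0.35) so it
    is compositionally distinct; the host decoy emulates the mapping
    reference used for host-read removal.
    """
    contam = simulate_ancestor(cfg.genome_length, 0.35, cfg.seed + 7919)
    contam = GenomeAssembly(
        "contaminant", [Contig("contaminant_c0", contam.contigs[0].seq)], "reference"
    )
    host = simulate_ancestor(cfg.genome_length, 0.41, cfg.seed + 104729)
    host = GenomeAssembly("host_decoy", [Contig("host_c0", host.contigs[0].seq)], "reference")
    return contam, host


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hit.size:
        orig = np.array([_BASE_INDEX.get(b.decode(), 0) for b in arr[hit]])
        arr[hit] = _BASES[(orig + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode()


def _uniform_fragment(
    contigs: list[Contig], length: int, rng: np.random.Generator
) -> tuple[str, str, int, int]:
    """A fragment of ``length`` bp drawn uniformly from the concatenated contigs."""
    lens = np.array([max(len(c) - length, 0) + 1 for c in contigs], dtype=float)
    ci = int(rng.choice(len(contigs), p=lens / lens.sum()))
    c = contigs[ci]
    start = int(rng.integers(0, max(len(c) - length, 0) + 1))
    end = min(start + length, len(c))
    return c.contig_id, c.seq[start:end], start, end


def simulate_sag(
    strain: GenomeAssembly,
    cfg: SimulationConfig,
    sag_seed: int,
    sag_id: str | None = None,
    aux: tuple[GenomeAssembly, GenomeAssembly] | None = None,
) -> tuple[GenomeAssembly, ReadSet, TruthManifest]:
    """Simulate one SAG from a strain genome.

    Steps: (i) per-SAG substitutions bring pairwise within-strain identity to
    ``cfg.within_strain_ani``; (ii) contiguous dropout windows are removed
    until the retained fraction matches ``cfg.target_completeness`` (true
    completeness, recorded in the manifest); (iii) retained runs become the
    SAG's contigs; (iv) reads are sampled with lognormal per-window depth,
    substitution errors, chimeric joins, contaminant and host reads, all
    flagged in the manifest.
    """
    sag_id = sag_id or f"{strain.sag_id}_sag{sag_seed % 1000}"
    s_mut, s_drop, s_reads = _child_seeds(sag_seed, 3)
    per_sag_div = (1.0 - cfg.within_strain_ani) / 2.0
    genome = mutate_to_ani(strain, 1.0 - per_sag_div, s_mut, derived_id=sag_id)
    gseq = genome.contigs[0].seq
    glen = len(gseq)

    # --- dropout: drop whole windows, keep contiguous runs as contigs
    rng = np.random.default_rng(s_drop)
    w = cfg.dropout_window
    n_windows = max(1, glen // w)
    n_drop = int(round((1.0 - cfg.target_completeness) * n_windows))
    n_drop = min(n_drop, n_windows - 1) if cfg.target_completeness > 0 else n_windows
    dropped = set(rng.choice(n_windows, size=n_drop, replace=False).tolist())
    bounds = [i * w for i in range(n_windows)] + [glen]
    dropped_iv = sorted((bounds[i], bounds[i + 1]) for i in dropped)
    contigs: list[Contig] = []
    run_start = None
    for i in range(n_windows + 1):
        if i < n_windows and i not in dropped:
            if run_start is None:
                run_start = bounds[i]
        else:
            if run_start is not None:
                s, e = run_start, bounds[i]
                contigs.append(Contig(f"{sag_id}_c{len(contigs)}", gseq[s:e]))
                run_start = None
    assembly = GenomeAssembly(sag_id, contigs, source="sag")
    retained = assembly.total_length
    truth = TruthManifest(
        sag_strain={sag_id: strain.sag_id},
        dropped_intervals={sag_id: dropped_iv},
        true_completeness={sag_id: retained / glen},
    )

    # --- reads
    rng = np.random.default_rng(s_reads)
    n_reads = int(round(cfg.mean_depth * retained / cfg.read_length))
    reads: list[Read] = []
    if n_reads > 0 and retained >= cfg.read_length:
        if cfg.contam_rate > 0 or cfg.host_decoy_rate > 0:
            contam, host = aux if aux is not None else auxiliary_genomes(cfg)
        else:
            contam = host = None
        # lognormal window weights (mean 1) over retained windows per contig
        windows: list[tuple[int, int, int]] = []  # (contig_idx, start, end)
        for ci, c in enumerate(assembly.contigs):
            for s in range(0, len(c), w):
                windows.append((ci, s, min(s + w, len(c))))
        weights = rng.lognormal(
            mean=-(cfg.lognormal_sigma**2) / 2, sigma=cfg.lognormal_sigma, size=len(windows)
        ) * np.array([e - s for _, s, e in windows])
        weights /= weights.sum()
        rl = cfg.read_length
        kinds = rng.random(n_reads)
        win_choice = rng.choice(len(windows), size=n_reads, p=weights)
        for i in range(n_reads):
            rid = f"{sag_id}_r{i:06d}"
            u = kinds[i]
            if u < cfg.host_decoy_rate and host is not None:
                cid, seq, s, e = _uniform_fragment(host.contigs, rl, rng)
                row = ManifestRow(rid, sag_id, strain.sag_id, cid, s, e, False, None, False, True)
            elif u < cfg.host_decoy_rate + cfg.contam_rate and contam is not None:
                cid, seq, s, e = _uniform_fragment(contam.contigs, rl, rng)
                row = ManifestRow(rid, sag_id, strain.sag_id, cid, s, e, False, None, True, False)
            else:
                ci, ws, we = windows[win_choice[i]]
                c = assembly.contigs[ci]
                start = int(rng.integers(ws, we))
                start = min(start, max(len(c) - rl, 0))
                end = min(start + rl, len(c))
                seq = c.seq[start:end]
                if u < cfg.host_decoy_rate + cfg.contam_rate + cfg.chimera_rate:
                    # chimera: first segment from this locus, second from a
                    # uniform random locus and strand
                    split = int(round(len(seq) * rng.uniform(0.25, 0.75)))
                    _, seq2, _, _ = _uniform_fragment(assembly.contigs, len(seq) - split, rng)
                    if rng.random() < 0.5:
                        seq2 = revcomp(seq2)
                    seq = seq[:split] + seq2
                    row = ManifestRow(
                        rid, sag_id, strain.sag_id, c.contig_id, start, start + split,
                        True, split, False, False,
                    )
                else:
                    row = ManifestRow(
                        rid, sag_id, strain.sag_id, c.contig_id, start, end,
                        False, None, False, False,
                    )
            seq = _apply_errors(seq, rng, cfg.error_rate)
            quals = [30] * len(seq)
            if cfg.degraded_read_fraction > 0 and rng.random() < cfg.degraded_read_fraction:
                tail = len(seq) // 4
                if tail:
                    quals[-tail:] = [2] * tail
            reads.append(Read(rid, seq, quals))
            truth.rows.append(row)
    return assembly, ReadSet(sag_id, reads), truth


@dataclass
class Cohort:
    """A simulated multi-host cohort: strains, per-SAG assemblies and reads,
    markers, auxiliary genomes, and the full truth manifest."""

    cfg: SimulationConfig
    ancestor: GenomeAssembly
    strains: list[GenomeAssembly]
    markers: GenomeAssembly
    assemblies: dict[str, GenomeAssembly]
    readsets: dict[str, ReadSet]
    manifest: TruthManifest
    host_of: dict[str, str]
    contaminant: GenomeAssembly
    host_decoy: GenomeAssembly


def simulate_cohort(
    cfg: SimulationConfig,
    host_strains: Sequence[Sequence[int]] | None = None,
) -> Cohort:
    """Simulate a cohort. ``host_strains`` maps each host to the strain
    indices it carries (a strain index appearing under two hosts emulates a
    shared strain between cohabiting hosts); default: one host with all
    strains. ``cfg.sags_per_strain`` SAGs are drawn per (host, strain)."""
    ancestor = simulate_ancestor(cfg.genome_length, cfg.gc_content, cfg.seed)
    markers, _ = plant_markers(
        ancestor, cfg.resolved_n_markers(), cfg.marker_length, cfg.seed + 13
    )
    strains = simulate_strains(cfg, ancestor)
    contam, host_decoy = auxiliary_genomes(cfg)
    if host_strains is None:
        host_strains = [list(range(cfg.n_strains))]
    assemblies: dict[str, GenomeAssembly] = {}
    readsets: dict[str, ReadSet] = {}
    manifest = TruthManifest()
    host_of: dict[str, str] = {}
    n_sags = sum(len(h) for h in host_strains) * cfg.sags_per_strain
    seeds = iter(_child_seeds(cfg.seed + 4242, n_sags))
    comp_rng = np.random.default_rng(cfg.seed + 9001)
    from dataclasses import replace as _replace

    for hi, strain_idxs in enumerate(host_strains):
        host_id = f"host{hi}"
        for si in strain_idxs:
            for j in range(cfg.sags_per_strain):
                sag_id = f"h{hi}_s{si}_sag{j}"
                sag_cfg = cfg
                if cfg.completeness_range is not None:
                    lo, hi_c = cfg.completeness_range
                    sag_cfg = _replace(
                        cfg, target_completeness=float(comp_rng.uniform(lo, hi_c)),
                        completeness_range=None,
                    )
                asm, rs, truth = simulate_sag(
                    strains[si], sag_cfg, next(seeds), sag_id=sag_id, aux=(contam, host_decoy)
                )
                assemblies[sag_id] = asm
                readsets[sag_id] = rs
                manifest.extend(truth)
                host_of[sag_id] = host_id
    return Cohort(
        cfg, ancestor, strains, markers, assemblies, readsets, manifest, host_of,
        contam, host_decoy,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Persist a cohort as FASTA/FASTQ/TSV/YAML under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "assemblies").mkdir(parents=True, exist_ok=True)
    (outdir / "reads").mkdir(exist_ok=True)
    for sag_id, asm in cohort.assemblies.items():
        write_fasta(asm, outdir / "assemblies" / f"{sag_id}.fa")
    for sag_id, rs in cohort.readsets.items():
        write_fastq(rs, outdir / "reads" / f"{sag_id}.fastq")
    write_fasta(cohort.markers, outdir / "markers.fa")
    write_fasta(cohort.host_decoy, outdir / "decoy.fa")
    cohort.manifest.to_tsv(outdir / "manifest.tsv")
    cfg_dict = asdict(cohort.cfg)
    if cfg_dict.get("completeness_range") is not None:
        cfg_dict["completeness_range"] = list(cfg_dict["completeness_range"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)
    with open(outdir / "hosts.tsv", "w") as fh:
        fh.write("sag_id\thost_id\tstrain_id\n")
        for sag_id, host in cohort.host_of.items():
            fh.write(f"{sag_id}\t{host}\t{cohort.manifest.sag_strain[sag_id]}\n")
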