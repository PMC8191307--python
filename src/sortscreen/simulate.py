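"""Generative model of a FACS-based pooled CRISPR enrichment screen.

The simulated experiment mirrors the canonical sorting screen: a cell pool
is transduced with a genome-scale knockout library at low MOI, selected,
and then repeatedly sorted on a fluorescence gate. A knockout of gene *g*
falls inside the gate with probability φ_g (the baseline, wild-type rate is
φ0); unedited cells behave like wild type. Between sorts the pool grows,
with per-gene relative fitness w_g, and the sorted subpopulation is
expanded back to the full population size. After the final round, amplicons
over the integrated guide cassette are sequenced as short single-end reads
whose spacer position varies because of a staggered primer.

Each guide *i* carries an editing efficiency ε_i drawn once per screen and
shared across replicates, so its expected sorted share in one round is

    n_i · [ε_i φ_g + (1 − ε_i) φ0]  /  Σ_j n_j · [ε_j φ_gj + (1 − ε_j) φ0].

Sorting processes a fixed number of cells per round; only the fraction in
the gate is collected, so a stringent gate bottlenecks library diversity
and most guides drift to extinction over the rounds while gate-enriched
(or merely lucky) clones take over — the structure real sorting screens
show after several rounds.

All stochastic steps (initial multinomial seeding, per-round sorting,
sequencing) flow from a single integer seed; replicate r uses
``seed + 1000·r``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counttable import CountTable, SampleStats, merge_counts
from .library import NONTARGETING_GENE, SgRNA, SgRNALibrary, write_library

#: Constant region of the staggered amplicon primer that precedes the spacer
#: in every read; exact-match counting keys on its 3' end.
ANCHOR_FULL = "TCTTGTGGAAAGGACGAAACACCG"
#: Last 9 nt of the constant region, immediately 5' of the spacer.
ANCHOR = "GAAACACCG"
#: Vector sequence 3' of the spacer (sgRNA scaffold); pads reads to length.
SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


#: Guide count of the GeCKO v2 human genome-scale knockout library.
GECKO_V2_SGRNAS = 123_411


def coverage_fold(n_cells: float, n_sgrnas: int = GECKO_V2_SGRNAS) -> float:
    """Cells-per-guide coverage of a pooled library (e.g. 4e7 cells over the
    GeCKO v2 library is >300x)."""
    if n_sgrnas <= 0:
        raise ValueError("n_sgrnas must be positive")
    return n_cells / n_sgrnas


class ConfigError(ValueError):
    """Raised for invalid screen configuration."""


@dataclass
class ScreenConfig:
    """Parameters of the simulated screen.

    Defaults follow the screen being emulated where it states a value:
    six guides per gene, MOI 0.4 (the screen used 0.3–0.5; single-infection
    approximation), 300 cells per guide at infection (>300x coverage), four
    sorting rounds, 71-nt single-end reads, primer stagger up to 8 nt.
    Gate stringency and sorted cell numbers are not reported by sorting
    screens of this design and are configurable; see docs/methods.md.
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 6
    n_nontargeting: int = 0
    moi: float = 0.4
    coverage: int = 300
    sort_rounds: int = 4
    gate_fraction: float = 0.005
    sorted_cells_per_round: int = 200_000
    reads_per_sample: int | None = None  # default: coverage * n_sgrnas
    read_length: int = 71
    stagger_max: int = 8
    seq_error_rate: float = 0.0
    library_skew_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "sgrnas_per_gene", "coverage", "sort_rounds",
                     "sorted_cells_per_round", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_nontargeting", "stagger_max"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.gate_fraction < 1.0:
            raise ConfigError(f"gate_fraction must be in [0, 1), got {self.gate_fraction}")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ConfigError(f"seq_error_rate must be in [0, 1], got {self.seq_error_rate}")
        if self.library_skew_sd < 0:
            raise ConfigError("library_skew_sd must be nonnegative")
        if self.moi <= 0:
            raise ConfigError("moi must be positive")
        if self.reads_per_sample is not None and self.reads_per_sample < 0:
            raise ConfigError("reads_per_sample must be nonnegative")
        min_len = self.stagger_max + len(ANCHOR_FULL) + 20
        if self.read_length < min_len:
            raise ConfigError(
                f"read_length {self.read_length} cannot hold stagger ({self.stagger_max}) "
                f"+ anchor ({len(ANCHOR_FULL)}) + 20-nt spacer = {min_len}"
            )

    @property
    def n_sgrnas(self) -> int:
        return self.n_genes * self.sgrnas_per_gene + self.n_nontargeting

    @property
    def population_size(self) -> int:
        return self.coverage * self.n_sgrnas

    def effective_reads_per_sample(self) -> int:
        return self.reads_per_sample if self.reads_per_sample is not None else self.population_size


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen.

    ``genes`` is indexed by gene symbol with columns ``phi`` (gate-survival
    probability of the knockout), ``fitness`` (per-round growth multiplier)
    and ``label`` in {neutral, hit, essential}. ``efficiency`` maps sgRNA id
    to its editing probability ε_i and is shared across replicates.
    """

    genes: pd.DataFrame
    efficiency: pd.Series

    def validate(self, gate_fraction: float) -> None:
        g = self.genes
        neutral = g["label"] == "neutral"
        if not np.allclose(g.loc[neutral, "phi"], gate_fraction):
            raise ValueError("neutral genes must have phi == gate_fraction")
        if not (g.loc[neutral, "fitness"] == 1.0).all():
            raise ValueError("neutral genes must have fitness == 1")
        if not (g.loc[g["label"] == "hit", "phi"] > gate_fraction).all():
            raise ValueError("hit genes must have phi > gate_fraction")
        if not (g.loc[g["label"] == "essential", "fitness"] < 1.0).all():
            raise ValueError("essential genes must have fitness < 1")
        if ((self.efficiency < 0) | (self.efficiency > 1)).any():
            raise ValueError("efficiencies must lie in [0, 1]")

    def to_files(self, gene_path: str | Path, sgrna_path: str | Path) -> None:
        out = self.genes.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(gene_path, sep="\t", index=False)
        eff = self.efficiency.rename("efficiency").rename_axis("sgrna_id").reset_index()
        eff.to_csv(sgrna_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, gene_path: str | Path, sgrna_path: str | Path) -> "ScreenTruth":
        genes = pd.read_csv(gene_path, sep="\t").set_index("gene")
        eff = pd.read_csv(sgrna_path, sep="\t").set_index("sgrna_id")["efficiency"]
        return cls(genes=genes, efficiency=eff)

    def hit_genes(self) -> list[str]:
        return self.genes.index[self.genes["label"] == "hit"].tolist()


@dataclass
class AbundanceState:
    """Expected per-sgRNA cell abundance at one timepoint, in library order."""

    abundance: np.ndarray
    population_size: float
    timepoint: str = "unsorted"

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if (self.abundance < 0).any():
            raise ValueError("abundances must be nonnegative")

    def proportions(self) -> np.ndarray:
        total = self.abundance.sum()
        if total <= 0:
            raise ValueError("empty population")
        return self.abundance / total


def make_library(cfg: ScreenConfig, rng: np.random.Generator | None = None) -> SgRNALibrary:
    """Synthesize a library: ``n_genes`` genes x ``sgrnas_per_gene`` guides
    plus ``n_nontargeting`` non-targeting controls, with unique random spacers."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_sgrnas
    spacers: set[str] = set()
    # rejection-sample unique 20-mers; collision probability is negligible
    while len(spacers) < n:
        block = rng.integers(0, 4, size=(n - len(spacers), 20))
        for row in block:
            spacers.add("".join("ACGT"[b] for b in row))
    spacer_list = sorted(spacers)
    rng.shuffle(spacer_list)
    entries: list[SgRNA] = []
    width = len(str(cfg.n_genes))
    k = 0
    for g in range(cfg.n_genes):
        gene = f"GENE{g + 1:0{width}d}"
        for j in range(cfg.sgrnas_per_gene):
            entries.append(SgRNA(id=f"{gene}_sg{j + 1}", gene=gene, spacer=spacer_list[k]))
            k += 1
    for j in range(cfg.n_nontargeting):
        entries.append(SgRNA(id=f"NTC_sg{j + 1}", gene=NONTARGETING_GENE, spacer=spacer_list[k]))
        k += 1
    return SgRNALibrary(entries=entries, name="simulated")


def make_truth(
    cfg: ScreenConfig,
    lib: SgRNALibrary,
    n_hits: int = 0,
    hit_phi: float = 0.3,
    n_essential: int = 0,
    essential_fitness: float = 0.5,
    efficiency_beta: tuple[float, float] = (8.0, 2.0),
    hit_genes: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> ScreenTruth:
    """Assign ground truth: hits get gate-survival ``hit_phi``, essential
    genes get growth multiplier ``essential_fitness``, everything else is
    neutral; per-guide efficiencies ε ~ Beta(a, b). Non-targeting controls
    are always neutral."""
    rng = rng or np.random.default_rng(cfg.seed)
    gene_names = lib.genes(include_nontargeting=True)
    targeting = [g for g in gene_names if g != NONTARGETING_GENE]
    if hit_genes is None:
        if n_hits > len(targeting):
            raise ConfigError(f"n_hits {n_hits} exceeds gene count {len(targeting)}")
        chosen = rng.choice(len(targeting), size=n_hits, replace=False)
        hit_genes = [targeting[i] for i in sorted(chosen)]
    hit_set = set(hit_genes)
    remaining = [g for g in targeting if g not in hit_set]
    if n_essential > len(remaining):
        raise ConfigError("n_essential exceeds available neutral genes")
    ess_idx = rng.choice(len(remaining), size=n_essential, replace=False)
    ess_set = {remaining[i] for i in ess_idx}

    phi, fitness, label = [], [], []
    for g in gene_names:
        if g in hit_set:
            phi.append(hit_phi); fitness.append(1.0); label.append("hit")
        elif g in ess_set:
            phi.append(cfg.gate_fraction); fitness.append(essential_fitness); label.append("essential")
        else:
            phi.append(cfg.gate_fraction); fitness.append(1.0); label.append("neutral")
    genes = pd.DataFrame(
        {"phi": phi, "fitness": fitness, "label": label},
        index=pd.Index(gene_names, name="gene"),
    )
    a, b = efficiency_beta
    eff = pd.Series(
        rng.beta(a, b, size=len(lib)),
        index=pd.Index(lib.ids, name="sgrna_id"),
        name="efficiency",
    )
    # non-targeting guides edit nothing that matters; efficiency is irrelevant
    truth = ScreenTruth(genes=genes, efficiency=eff)
    truth.validate(cfg.gate_fraction)
    return truth


def _truth_arrays(truth: ScreenTruth, lib: SgRNALibrary) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sgRNA (phi_g, w_g, eps_i) aligned to library order."""
    genes = [sg.gene for sg in lib]
    phi = truth.genes["phi"].reindex(genes).to_numpy()
    fit = truth.genes["fitness"].reindex(genes).to_numpy()
    eps = truth.efficiency.reindex(lib.ids).to_numpy()
    if np.isnan(phi).any() or np.isnan(eps).any():
        raise ValueError("truth does not cover every library gene/sgRNA")
    return phi, fit, eps


def simulate_initial_population(
    cfg: ScreenConfig,
    lib: SgRNALibrary,
    rng: np.random.Generator | None = None,
) -> AbundanceState:
    """Seed the post-selection pool: library proportions are log-normally
    skewed (sd ``library_skew_sd`` in natural log) and ``coverage x n_sgrnas``
    cells are drawn multinomially."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = len(lib)
    weights = np.exp(rng.normal(0.0, cfg.library_skew_sd, size=n)) if cfg.library_skew_sd > 0 else np.ones(n)
    p = weights / weights.sum()
    cells = rng.multinomial(cfg.population_size, p).astype(float)
    return AbundanceState(abundance=cells, population_size=cfg.population_size, timepoint="unsorted")


def simulate_sort_round(
    state: AbundanceState,
    truth: ScreenTruth,
    cfg: ScreenConfig,
    lib: SgRNALibrary,
    rng: np.random.Generator | None = None,
    round_index: int = 1,
    expectation: bool = False,
) -> AbundanceState:
    """One growth + sort + expansion cycle.

    Growth multiplies each guide's abundance by its gene's fitness w_g and
    renormalizes to the population size (relative fitness). The sort runs
    ``sorted_cells_per_round`` cells through the instrument (a multinomial
    draw over current proportions); each processed cell carrying guide i is
    collected with probability ε_i φ_g + (1−ε_i) φ0, so the expected
    collected share is proportional to n_i·[ε_i φ_g + (1−ε_i) φ0]. The
    collected pool is then expanded back to the population size. A tight
    gate over a diverse pool therefore bottlenecks the library — the drift
    that washes most guides out of a real sorting screen. With
    ``expectation=True`` both draws are replaced by their expectations
    (used for closed-form checks).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    phi, fit, eps = _truth_arrays(truth, lib)

    grown = state.abundance * fit
    total = grown.sum()
    if total <= 0:
        raise ValueError("population went extinct during growth")
    grown = grown * (state.population_size / total)

    survival = eps * phi + (1.0 - eps) * cfg.gate_fraction
    if not (survival > 0).any():
        raise ValueError("empty gate: all survival probabilities are zero")
    p = grown / grown.sum()
    if expectation:
        sorted_cells = cfg.sorted_cells_per_round * p * survival
    else:
        processed = rng.multinomial(cfg.sorted_cells_per_round, p)
        sorted_cells = rng.binomial(processed, survival).astype(float)
    stotal = sorted_cells.sum()
    if stotal <= 0:
        raise ValueError("no cells passed the gate")
    expanded = sorted_cells * (state.population_size / stotal)
    return AbundanceState(
        abundance=expanded,
        population_size=state.population_size,
        timepoint=f"sorted_round{round_index}",
    )


def _mutate_reads(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Apply iid per-base substitutions at the given rate."""
    if rate <= 0 or not seqs:
        return seqs
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # substitute with one of the three other bases
        orig = arr[hits]
        subs = _BASES[rng.integers(0, 4, size=hits.size)]
        clash = subs == orig
        while clash.any():
            subs[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = subs == orig
        arr[hits] = subs
    flat = arr.tobytes().decode()
    out, pos = [], 0
    for s in seqs:
        out.append(flat[pos:pos + len(s)])
        pos += len(s)
    return out


def simulate_sequencing(
    state: AbundanceState,
    lib: SgRNALibrary,
    cfg: ScreenConfig,
    sample_name: str,
    rng: np.random.Generator | None = None,
    fastq_path: str | Path | None = None,
) -> CountTable:
    """Sample reads multinomially over current guide proportions.

    Returns the exact tally as a single-column :class:`CountTable` (the
    oracle for read counting); if ``fastq_path`` is given, also writes the
    corresponding amplicon reads: random stagger (0..stagger_max nt) +
    constant anchor + 20-nt spacer + vector scaffold, truncated to
    ``read_length``, constant Phred quality 'I', with optional per-base
    substitution errors.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_reads = cfg.effective_reads_per_sample()
    p = state.proportions()
    tally = rng.multinomial(n_reads, p) if n_reads > 0 else np.zeros(len(lib), dtype=int)

    table = CountTable.from_counts(
        sgrna_ids=lib.ids,
        genes=[sg.gene for sg in lib],
        columns={sample_name: tally.astype(int)},
        stats={sample_name: SampleStats(total_reads=int(n_reads), unassigned=0)},
    )

    if fastq_path is not None:
        _write_fastq(fastq_path, lib, tally, cfg, sample_name, rng)
    return table


def _write_fastq(
    path: str | Path,
    lib: SgRNALibrary,
    tally: np.ndarray,
    cfg: ScreenConfig,
    sample_name: str,
    rng: np.random.Generator,
) -> None:
    qual = "I" * cfg.read_length
    total = int(tally.sum())
    staggers = rng.integers(0, cfg.stagger_max + 1, size=total)
    # random stagger bases drawn in one block
    stagger_bases = rng.integers(0, 4, size=int(staggers.sum()))
    sb_pos = 0
    seqs: list[str] = []
    for spacer, count in zip(lib.spacers, tally):
        core = ANCHOR_FULL + spacer + SCAFFOLD
        for _ in range(int(count)):
            slen = int(staggers[len(seqs)])
            stag = "".join("ACGT"[b] for b in stagger_bases[sb_pos:sb_pos + slen])
            sb_pos += slen
            seqs.append((stag + core)[: cfg.read_length])
    seqs = _mutate_reads(seqs, cfg.seq_error_rate, rng)
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{sample_name}.{i + 1}\n{seq}\n+\n{qual}\n")


@dataclass
class ScreenResult:
    """Everything one simulated screen produces."""

    config: ScreenConfig
    library: SgRNALibrary
    truth: ScreenTruth
    counts: CountTable                     # unsorted/sorted x replicates
    fastq_paths: dict[str, Path] = field(default_factory=dict)
    library_path: Path | None = None
    truth_paths: tuple[Path, Path] | None = None


def simulate_screen(
    cfg: ScreenConfig,
    truth: ScreenTruth | None = None,
    lib: SgRNALibrary | None = None,
    n_replicates: int = 2,
    outdir: str | Path | None = None,
    write_fastq: bool = False,
    **truth_overrides,
) -> ScreenResult:
    """Run the full screen for ``n_replicates`` replicates sharing one
    ground truth but with independent stochastic draws (replicate r is
    seeded with ``seed + 1000·r``).

    Keyword overrides (``n_hits``, ``hit_phi``, ``n_essential``, ...) are
    forwarded to :func:`make_truth` when no truth is supplied. With
    ``outdir`` set, writes the library CSV, truth TSVs, a JSON manifest and
    (if ``write_fastq``) per-sample FASTQ files.
    """
    rng0 = np.random.default_rng(cfg.seed)
    if lib is None:
        lib = make_library(cfg, rng0)
    if truth is None:
        truth = make_truth(cfg, lib, rng=rng0, **truth_overrides)
    elif truth_overrides:
        raise TypeError("truth_overrides are only valid when truth is None")
    truth.validate(cfg.gate_fraction)

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    columns: list[CountTable] = []
    fastq_paths: dict[str, Path] = {}
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(cfg.seed + 1000 * rep)
        state = simulate_initial_population(cfg, lib, rng)
        name_u = f"unsorted_rep{rep}"
        fq_u = outdir / f"{name_u}.fastq" if (outdir and write_fastq) else None
        columns.append(simulate_sequencing(state, lib, cfg, name_u, rng, fastq_path=fq_u))
        if fq_u:
            fastq_paths[name_u] = fq_u
        for r in range(1, cfg.sort_rounds + 1):
            state = simulate_sort_round(state, truth, cfg, lib, rng, round_index=r)
        name_s = f"sorted_rep{rep}"
        fq_s = outdir / f"{name_s}.fastq" if (outdir and write_fastq) else None
        columns.append(simulate_sequencing(state, lib, cfg, name_s, rng, fastq_path=fq_s))
        if fq_s:
            fastq_paths[name_s] = fq_s

    counts = merge_counts(columns)
    result = ScreenResult(config=cfg, library=lib, truth=truth, counts=counts, fastq_paths=fastq_paths)

    if outdir is not None:
        lib_path = outdir / "library.csv"
        write_library(lib, lib_path)
        gene_path, sg_path = outdir / "truth_genes.tsv", outdir / "truth_sgrnas.tsv"
        truth.to_files(gene_path, sg_path)
        counts.to_tsv(outdir / "counts.tsv")
        manifest = {
            "config": asdict(cfg),
            "n_replicates": n_replicates,
            "samples": counts.samples,
            "fastq": {k: str(v) for k, v in fastq_paths.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        result.library_path = lib_path
        result.truth_paths = (gene_path, sg_path)
    return result


def replicate_pairs(counts: CountTable) -> list[tuple[str, str]]:
    """Infer (unsorted, sorted) sample pairs from standard sample names."""
    pairs = []
    for s in counts.samples:
        if s.startswith("unsorted_"):
            mate = "sorted_" + s[len("unsorted_"):]
            if mate in counts.samples:
                pairs.append((s, mate))
    if not pairs:
        raise ValueError(f"no unsorted_/sorted_ sample pairs found in {counts.samples}")
    return pairs
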