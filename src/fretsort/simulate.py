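"""Synthetic-data generators for every pipeline stage.

The cytometry generator draws per-cell channel intensities from an explicit
photophysical model of a 1:1 donor-acceptor fusion:

    I1 = N * k_D1 * (1 - E)                       (donor channel)
    I2 = N * (k_D2*(1 - E) + k_A2 + E*k_sen)      (FRET channel)
    I3 = N * k_A3                                 (acceptor channel)

where ``N`` is the per-cell number of biosensor molecules (lognormal across
the population), ``E`` the true transfer efficiency, the ``k`` constants are
per-molecule channel brightnesses, and each channel additionally receives
multiplicative Gaussian measurement noise and additive autofluorescence
background.  By construction the implied correction factors are exact:
S1 = k_D2/k_D1, S2 = k_A2/k_A3, alpha = k_sen/k_D1, so the sensitized-emission
estimator has an analytic oracle and noise-free samples are exactly invertible.

The screen generator models a barcoded mutant library in which each gene
multiplies the cellular c-di-GMP level, the biosensor translates concentration
into FRET via a Hill curve, and FACS selects the tails of the FRET/donor
ratio.  Gate probabilities are computed probabilistically (Gaussian-mixture
log-ratio model per mutant; population tail threshold by root finding), pools
are re-gated each cycle, and sequencing reads are drawn multinomially from the
final pool composition and written as adapter-flanked FASTQ.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .binding import KineticsTrace, Titration, hill
from .cytofret import EventTable
from .sortseq import U1_ADAPTER, U2_ADAPTER, LibraryMap, reverse_complement

_STOICHIOMETRIES = ("fusion", "donor_only", "acceptor_only", "background")


@dataclass(frozen=True)
class PhotophysicsConfig:
    """Brightness constants and noise levels of the cytometry generator.

    Brightnesses are in arbitrary units per molecule; backgrounds in the same
    units per event.  ``expr_log_mean``/``expr_log_sd`` parameterize the
    lognormal population distribution of biosensor copy number;
    ``measurement_cv`` is the per-channel multiplicative measurement noise.
    """

    k_d1: float = 1.0
    k_d2: float = 0.55
    k_a2: float = 0.45
    k_a3: float = 1.5
    k_sen: float = 0.739
    bg_mean: tuple[float, float, float] = (30.0, 25.0, 40.0)
    bg_sd: tuple[float, float, float] = (8.0, 7.0, 10.0)
    expr_log_mean: float = math.log(5000.0)
    expr_log_sd: float = 0.4
    measurement_cv: float = 0.05

    def __post_init__(self) -> None:
        if min(self.k_d1, self.k_d2, self.k_a2, self.k_a3, self.k_sen) <= 0:
            raise ValueError("brightness constants must be positive")

    @property
    def s1_true(self) -> float:
        return self.k_d2 / self.k_d1

    @property
    def s2_true(self) -> float:
        return self.k_a2 / self.k_a3

    @property
    def alpha_true(self) -> float:
        return self.k_sen / self.k_d1

    def noise_free(self) -> "PhotophysicsConfig":
        """Variant with zero background and zero measurement noise."""
        return replace(
            self, bg_mean=(0.0, 0.0, 0.0), bg_sd=(0.0, 0.0, 0.0), measurement_cv=0.0
        )


def simulate_cytometry(
    cfg: PhotophysicsConfig,
    e_true: float,
    n_events: int = 30000,
    stoichiometry: str = "fusion",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> EventTable:
    """Draw one cytometry sample from the photophysical model.

    ``stoichiometry`` selects a 1:1 fusion, a donor-only or acceptor-only
    control (for which ``e_true`` must be 0), or a pure-background
    (empty-vector) sample.
    """
    if stoichiometry not in _STOICHIOMETRIES:
        raise ValueError(f"unknown stoichiometry {stoichiometry!r}")
    if not (0.0 <= e_true < 1.0):
        raise ValueError("e_true must be in [0, 1)")
    if stoichiometry != "fusion" and e_true != 0.0:
        raise ValueError(f"{stoichiometry} samples cannot transfer (e_true must be 0)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = int(n_events)
    N = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, n)
    has_donor = stoichiometry in ("fusion", "donor_only")
    has_acceptor = stoichiometry in ("fusion", "acceptor_only")
    nd = N if has_donor else np.zeros(n)
    na = N if has_acceptor else np.zeros(n)
    sen = N * e_true * cfg.k_sen if stoichiometry == "fusion" else np.zeros(n)
    sig1 = nd * cfg.k_d1 * (1.0 - e_true)
    sig2 = nd * cfg.k_d2 * (1.0 - e_true) + na * cfg.k_a2 + sen
    sig3 = na * cfg.k_a3
    events = np.empty((n, 3))
    for j, sig in enumerate((sig1, sig2, sig3)):
        noise = rng.normal(1.0, cfg.measurement_cv, n) if cfg.measurement_cv > 0 else 1.0
        bg = (
            rng.normal(cfg.bg_mean[j], cfg.bg_sd[j], n)
            if cfg.bg_sd[j] > 0
            else cfg.bg_mean[j]
        )
        events[:, j] = sig * noise + bg
    return EventTable(
        sample_id=sample_id or f"sim_{stoichiometry}_E{e_true:g}", events=events
    )


@dataclass(frozen=True)
class CalibrationSet:
    """Samples needed for a full spectral calibration, plus the ground truth."""

    fusion_samples: tuple[EventTable, ...]
    donor_only: EventTable
    acceptor_only: EventTable
    background: EventTable
    e_values: tuple[float, ...]
    alpha_true: float
    s1_true: float
    s2_true: float


def simulate_calibration_set(
    cfg: PhotophysicsConfig,
    e_list,
    n_events: int = 30000,
    seed: int | None = None,
) -> CalibrationSet:
    """One fusion sample per efficiency plus the three control samples."""
    rng = np.random.default_rng(seed)
    fusions = tuple(
        simulate_cytometry(
            cfg, e, n_events, "fusion", rng=rng, sample_id=f"calib_E{e:g}"
        )
        for e in e_list
    )
    donor = simulate_cytometry(cfg, 0.0, n_events, "donor_only", rng=rng)
    acceptor = simulate_cytometry(cfg, 0.0, n_events, "acceptor_only", rng=rng)
    background = simulate_cytometry(cfg, 0.0, n_events, "background", rng=rng)
    return CalibrationSet(
        fusion_samples=fusions,
        donor_only=donor,
        acceptor_only=acceptor,
        background=background,
        e_values=tuple(float(e) for e in e_list),
        alpha_true=cfg.alpha_true,
        s1_true=cfg.s1_true,
        s2_true=cfg.s2_true,
    )


def simulate_titration(
    kd: float,
    h: float,
    e0: float,
    e_inf: float,
    doses,
    noise_sd: float = 0.0,
    seed: int | None = None,
    response_kind: str = "efficiency",
) -> Titration:
    """Hill-model titration with optional Gaussian response noise."""
    doses = np.asarray(doses, dtype=float)
    resp = hill(doses, kd, h, e0, e_inf)
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, doses.shape)
    return Titration(concentration=doses, response=resp, response_kind=response_kind)


def simulate_kinetics(
    k_off: float,
    r0: float,
    r_inf: float,
    t_removal: float = 5.0,
    duration: float = 40.0,
    dt: float = 0.25,
    noise_sd: float = 0.0,
    seed: int | None = None,
    addition_concentration: float = 1000.0,
) -> KineticsTrace:
    """Ratiometric washout trace: plateau at R0, exponential decay after removal."""
    if k_off < 0:
        raise ValueError("k_off must be >= 0")
    t = np.arange(0.0, duration + dt / 2, dt)
    ratio = np.where(
        t <= t_removal, r0, r_inf + (r0 - r_inf) * np.exp(-k_off * (t - t_removal))
    )
    if noise_sd > 0:
        ratio = ratio + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    events = (
        (0.0, "addition", addition_concentration),
        (float(t_removal), "removal", 0.0),
    )
    return KineticsTrace(time=t, ratio=ratio, events=events)


# ---------------------------------------------------------------------------
# FACS sort-seq screen


@dataclass(frozen=True)
class SortSimConfig:
    """Study conditions of the simulated FRET-To-Sort screen.

    Each gene's mutant multiplies the cellular c-di-GMP level by its effect
    (1 = neutral).  Cells of a mutant carry lognormal cell-to-cell ligand
    variation around that level; the biosensor maps concentration to FRET via
    the Hill parameters, and sorting selects the ``gate_fraction`` tails of
    the FRET/donor ratio.  If ``effects`` is not given, ``n_causal`` genes are
    drawn with log-uniform multipliers in ``causal_effect_range`` (half
    increasing, half decreasing c-di-GMP).

    ``sort_impurity`` is the fraction of collected cells that are
    gate-independent carryover (imperfect sort purity); it bounds how strongly
    a mutant can be depleted from the opposite tail, as on a real sorter.
    ``fitness`` optionally assigns per-gene growth multipliers applied during
    the regrowth between sorting cycles (default: neutral growth).
    """

    n_genes: int = 2000
    barcodes_per_gene: int = 3
    effects: dict[int, float] | None = None
    n_causal: int = 20
    causal_effect_range: tuple[float, float] = (4.0, 16.0)
    baseline_nM: float = 100.0
    cell_log_sd: float = 0.35
    sensor_kd: float = 100.0
    sensor_h: float = 1.0
    sensor_e0: float = 18.0
    sensor_e_inf: float = 38.0
    gate_fraction: float = 0.015
    sort_impurity: float = 0.02
    n_cycles: int = 1
    sequenced_cycles: tuple[int, ...] | None = None
    reads_per_pool: int = 1_000_000
    n_replicates: int = 2
    fitness: dict[int, float] | None = None
    barcode_log_sd: float = 0.5
    biosensor_label: str = "simC3"

    def __post_init__(self) -> None:
        if not (0.0 < self.gate_fraction <= 1.0):
            raise ValueError("gate_fraction must be in (0, 1]")
        if not (0.0 <= self.sort_impurity < 1.0):
            raise ValueError("sort_impurity must be in [0, 1)")
        if not (1 <= self.n_cycles <= 3):
            raise ValueError("n_cycles must be 1..3")
        if self.effects is not None and any(e <= 0 for e in self.effects.values()):
            raise ValueError("effects must be positive multipliers")
        if self.fitness is not None and any(f <= 0 for f in self.fitness.values()):
            raise ValueError("fitness multipliers must be positive")


@dataclass(frozen=True)
class SortSimTruth:
    """Ground truth of a simulated screen: per-gene effects, directions and
    the expected per-cycle gate probabilities of each tail."""

    table: pd.DataFrame  # index gene; effect, direction, p_high_x*, p_low_x*


@dataclass(frozen=True)
class SortSimResult:
    """File layout and ground truth of one written screen."""

    out_dir: Path
    fastq_paths: dict[str, Path]
    library_map_path: Path
    sample_sheet_path: Path
    truth_path: Path
    sample_sheet: pd.DataFrame
    library_map: LibraryMap
    truth: SortSimTruth


def ratio_of_efficiency(photo: PhotophysicsConfig, e_frac) -> np.ndarray:
    """Background-free FRET/donor ratio of a fusion at efficiency ``e`` (fraction)."""
    e = np.asarray(e_frac, dtype=float)
    return (photo.k_d2 * (1 - e) + photo.k_a2 + photo.k_sen * e) / (
        photo.k_d1 * (1 - e)
    )


def _gate_model(cfg: SortSimConfig, photo: PhotophysicsConfig, effects: np.ndarray):
    """Per-gene Gaussian-mixture model of the log FRET ratio.

    Returns (mu, wq, s): node means (genes x nodes) from Gauss-Hermite
    quadrature over the per-cell lognormal ligand level, node weights, and the
    measurement noise SD of the log ratio (difference of two channels with
    multiplicative CV noise).
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(15)
    log_c = (
        np.log(cfg.baseline_nM)
        + np.log(effects)[:, None]
        + cfg.cell_log_sd * nodes[None, :]
    )
    wq = weights / weights.sum()
    e_pct = hill(
        np.exp(log_c), cfg.sensor_kd, cfg.sensor_h, cfg.sensor_e0, cfg.sensor_e_inf
    )
    mu = np.log(ratio_of_efficiency(photo, e_pct / 100.0))
    s = max(math.sqrt(2.0) * photo.measurement_cv, 1e-6)
    return mu, wq, s


def _tail_probs(thr: float, mu: np.ndarray, wq: np.ndarray, s: float, tail: str):
    z = (thr - mu) / s
    per_node = stats.norm.sf(z) if tail == "high" else stats.norm.cdf(z)
    return per_node @ wq


def _tail_threshold(
    f_gene: np.ndarray, mu: np.ndarray, wq: np.ndarray, s: float,
    fraction: float, tail: str,
) -> float:
    lo = float(mu.min() - 12 * s)
    hi = float(mu.max() + 12 * s)

    def excess(thr: float) -> float:
        return float(f_gene @ _tail_probs(thr, mu, wq, s, tail)) - fraction

    return optimize.brentq(excess, lo, hi, xtol=1e-12)


def gate_probabilities(
    cfg: SortSimConfig,
    photo: PhotophysicsConfig,
    effects: np.ndarray,
    f_gene: np.ndarray,
    tail: str,
) -> np.ndarray:
    """Probability that a cell of each gene falls inside the selected tail gate
    of the current pool (gene frequencies ``f_gene``)."""
    if cfg.gate_fraction >= 1.0:
        return np.ones(len(effects))
    mu, wq, s = _gate_model(cfg, photo, effects)
    thr = _tail_threshold(f_gene, mu, wq, s, cfg.gate_fraction, tail)
    return _tail_probs(thr, mu, wq, s, tail)


def collection_probabilities(
    cfg: SortSimConfig,
    photo: PhotophysicsConfig,
    effects: np.ndarray,
    f_gene: np.ndarray,
    tail: str,
) -> np.ndarray:
    """Per-gene probability of ending up in the collected pool: the tail-gate
    probability blended with the gate-independent carryover of an imperfectly
    pure sort.  For a fully neutral library this equals the gate fraction for
    every gene, so all enrichments are 1 in expectation."""
    p = gate_probabilities(cfg, photo, effects, f_gene, tail)
    imp = cfg.sort_impurity
    return (1.0 - imp) * p + imp * cfg.gate_fraction


def _draw_effects(cfg: SortSimConfig, rng: np.random.Generator) -> np.ndarray:
    effects = np.ones(cfg.n_genes)
    if cfg.effects is not None:
        for idx, eff in cfg.effects.items():
            effects[idx] = eff
        return effects
    causal = rng.choice(cfg.n_genes, size=cfg.n_causal, replace=False)
    lo, hi = np.log(cfg.causal_effect_range)
    mag = np.exp(rng.uniform(lo, hi, cfg.n_causal))
    n_up = cfg.n_causal // 2
    effects[causal[:n_up]] = mag[:n_up]
    effects[causal[n_up:]] = 1.0 / mag[n_up:]
    return effects


def _random_barcodes(n: int, rng: np.random.Generator, length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        for bc in ["".join(row) for row in bases[rng.integers(0, 4, (n - len(out), length))]]:
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _simulate_screen(cfg: SortSimConfig, photo: PhotophysicsConfig, seed: int | None):
    """Core screen simulation at barcode resolution.

    Returns (barcodes, gene_names, gene_of_barcode, pool_counts, samples_meta,
    truth).  ``pool_counts`` maps sample_id -> integer read counts per barcode.
    """
    rng = np.random.default_rng(seed)
    G, B = cfg.n_genes, cfg.barcodes_per_gene
    gene_names = [f"g{i + 1:04d}" for i in range(G)]
    effects = _draw_effects(cfg, rng)
    barcodes = _random_barcodes(G * B, rng)
    gene_idx_of_bc = np.repeat(np.arange(G), B)

    fitness = np.ones(G)
    if cfg.fitness is not None:
        for idx, f in cfg.fitness.items():
            fitness[idx] = f

    sequenced = (
        tuple(range(1, cfg.n_cycles + 1))
        if cfg.sequenced_cycles is None
        else tuple(cfg.sequenced_cycles)
    )
    if any(c < 1 or c > cfg.n_cycles for c in sequenced):
        raise ValueError("sequenced_cycles outside 1..n_cycles")

    # nominal (equal-abundance) expectations for the truth table
    truth_cols: dict[str, np.ndarray] = {}
    f_nom = {tail: np.full(G, 1.0 / G) for tail in ("high", "low")}
    for cyc in range(1, cfg.n_cycles + 1):
        for tail in ("high", "low"):
            p = collection_probabilities(cfg, photo, effects, f_nom[tail], tail)
            truth_cols[f"p_{tail}_x{cyc}"] = p
            upd = f_nom[tail] * p
            f_nom[tail] = upd / upd.sum()
    increasing = cfg.sensor_e_inf > cfg.sensor_e0
    direction = np.where(
        effects == 1.0,
        "none",
        np.where((effects > 1.0) == increasing, "high", "low"),
    )
    truth = SortSimTruth(
        pd.DataFrame(
            {"effect": effects, "direction": direction, **truth_cols},
            index=pd.Index(gene_names, name="gene"),
        )
    )

    pool_counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for rep in range(1, cfg.n_replicates + 1):
        f_bc = rng.lognormal(0.0, cfg.barcode_log_sd, G * B)
        f_bc /= f_bc.sum()
        sid = f"r{rep}_unsorted"
        pool_counts[sid] = rng.multinomial(cfg.reads_per_pool, f_bc)
        meta_rows.append((sid, "unsorted", 0, rep, cfg.biosensor_label))
        for tail in ("high", "low"):
            f_tail = f_bc.copy()
            for cyc in range(1, cfg.n_cycles + 1):
                f_gene = np.bincount(gene_idx_of_bc, weights=f_tail, minlength=G)
                p = collection_probabilities(cfg, photo, effects, f_gene, tail)
                f_tail = f_tail * p[gene_idx_of_bc]
                f_tail /= f_tail.sum()
                if cyc in sequenced:
                    sid = f"r{rep}_{tail}_x{cyc}"
                    pool_counts[sid] = rng.multinomial(cfg.reads_per_pool, f_tail)
                    meta_rows.append(
                        (sid, f"{tail}_sorted", cyc, rep, cfg.biosensor_label)
                    )
                if cyc < cfg.n_cycles:
                    # regrowth before the next sort, with optional per-gene
                    # fitness differences
                    f_tail = f_tail * fitness[gene_idx_of_bc]
                    f_tail /= f_tail.sum()
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "role", "cycle", "replicate", "biosensor"]
    ).set_index("sample_id")
    return barcodes, gene_names, gene_idx_of_bc, pool_counts, samples, truth


def simulate_sort_counts(
    cfg: SortSimConfig,
    photo: PhotophysicsConfig | None = None,
    seed: int | None = None,
):
    """Simulate a screen and return gene-level counts directly (no FASTQ).

    Returns (CountTable, SortSimTruth).  Useful for fast statistical checks;
    :func:`simulate_library_sort` writes the full FASTQ + map + sheet layout.
    """
    from .sortseq import CountTable

    photo = photo or PhotophysicsConfig()
    _, gene_names, gene_idx, pool_counts, samples, truth = _simulate_screen(
        cfg, photo, seed
    )
    data = {
        sid: np.bincount(gene_idx, weights=c, minlength=cfg.n_genes).astype(np.int64)
        for sid, c in pool_counts.items()
    }
    counts = pd.DataFrame(data, index=pd.Index(gene_names, name="gene"))
    return CountTable(counts=counts, samples=samples), truth


def _write_fastq(
    path: Path,
    pool: str,
    counts: np.ndarray,
    barcodes: list[str],
    rng: np.random.Generator,
    pad_lengths: tuple[int, int] = (4, 6),
) -> None:
    """Write one pool as gzip FASTQ: pad5 + U1 + revcomp(barcode) + U2 + pad3, Q40."""
    bases = "ACGT"
    seqs = []
    for bc in barcodes:
        pad5 = "".join(bases[i] for i in rng.integers(0, 4, pad_lengths[0]))
        pad3 = "".join(bases[i] for i in rng.integers(0, 4, pad_lengths[1]))
        seqs.append(pad5 + U1_ADAPTER + reverse_complement(bc) + U2_ADAPTER + pad3)
    quals = ["I" * len(s) for s in seqs]
    order = np.repeat(np.arange(len(barcodes)), counts)
    with gzip.open(path, "wt", compresslevel=1) as fh:
        write = fh.write
        chunk: list[str] = []
        for i, b in enumerate(order):
            chunk.append(f"@{pool}_{i}\n{seqs[b]}\n+\n{quals[b]}\n")
            if len(chunk) == 20000:
                write("".join(chunk))
                chunk.clear()
        write("".join(chunk))


def simulate_library_sort(
    cfg: SortSimConfig,
    photo: PhotophysicsConfig | None = None,
    out_dir: str | Path = ".",
    seed: int | None = None,
) -> SortSimResult:
    """Simulate a full screen and write FASTQ pools, library map, sample sheet
    and ground-truth table to ``out_dir``."""
    photo = photo or PhotophysicsConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    barcodes, gene_names, gene_idx, pool_counts, samples, truth = _simulate_screen(
        cfg, photo, seed
    )
    pad_rng = np.random.default_rng(
        np.random.SeedSequence([0 if seed is None else int(seed), 7])
    )

    map_path = out / "library_map.tsv"
    lib_df = pd.DataFrame(
        {
            "barcode": barcodes,
            "gene": [gene_names[i] for i in gene_idx],
            "insertion_location": [
                f"chr1:{1000 + 50 * i}" for i in range(len(barcodes))
            ],
            "intergenic": 0,
        }
    )
    lib_df.to_csv(map_path, sep="\t", index=False)

    fastq_paths: dict[str, Path] = {}
    for sid, counts in pool_counts.items():
        fq = out / f"{sid}.fastq.gz"
        _write_fastq(fq, sid, counts, barcodes, pad_rng)
        fastq_paths[sid] = fq

    sheet = samples.reset_index()
    sheet.insert(1, "fastq", [str(fastq_paths[s]) for s in sheet["sample_id"]])
    sheet_path = out / "samples.csv"
    sheet.to_csv(sheet_path, index=False)

    truth_path = out / "truth.tsv"
    truth.table.to_csv(truth_path, sep="\t")

    return SortSimResult(
        out_dir=out,
        fastq_paths=fastq_paths,
        library_map_path=map_path,
        sample_sheet_path=sheet_path,
        truth_path=truth_path,
        sample_sheet=sheet,
        library_map=LibraryMap(records=lib_df),
        truth=truth,
    )
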