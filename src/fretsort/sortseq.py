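"""FRET-based sort-seq enrichment analysis for barcoded transposon libraries.

A randomly barcoded Tn5 mutant library expressing a c-di-GMP FRET biosensor is
FACS-sorted on the tails of the FRET/donor ratio; barcodes amplified from the
sorted and unsorted pools are sequenced, counted and mapped to genes.  A gene's
enrichment in a sorted pool is its depth-normalized read fraction divided by
the same quantity in the matched unsorted library, and the screen statistic is
the log2 ratio of high-pool over low-pool enrichment, tested across replicates
with a Bayesian-regularized unpaired t-test (Cyber-T) that pools variance
information across genes of similar abundance — the regularization that makes
two biological replicates usable.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import stats

#: Flanking adapter sequences of the barcode amplicon.
U1_ADAPTER = "GTCGACCTGCAGCGTACG"
U2_ADAPTER = "AGAGACCTCGTGGACATC"

#: Default read filter: a gene is excluded when below this raw read count.
MIN_READS = 200

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class LibraryMap:
    """Barcode -> gene map of the transposon mutant library."""

    records: pd.DataFrame  # columns: barcode, gene, insertion_location, intergenic

    def __post_init__(self) -> None:
        df = self.records
        required = {"barcode", "gene"}
        if not required.issubset(df.columns):
            raise ValueError(f"library map needs columns {sorted(required)}")
        if df["barcode"].duplicated().any():
            raise ValueError("library map barcodes are not unique")
        bad = ~df["barcode"].str.fullmatch("[ACGT]+")
        if bad.any():
            raise ValueError("library map barcodes must be ACGT-only")

    @property
    def barcode_to_gene(self) -> dict[str, str]:
        return dict(zip(self.records["barcode"], self.records["gene"]))

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.records["gene"]))


@dataclass
class BarcodeCounts:
    """Barcode read counts of one sample plus read-accounting tallies."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_reads_total: int = 0
    n_discarded_no_adapter: int = 0
    n_discarded_short: int = 0
    n_discarded_quality: int = 0
    n_unmatched: int = 0

    @property
    def n_counted(self) -> int:
        return sum(self.counts.values())

    def check_accounting(self) -> None:
        acc = (
            self.n_counted
            + self.n_discarded_no_adapter
            + self.n_discarded_short
            + self.n_discarded_quality
        )
        if acc != self.n_reads_total:
            raise AssertionError(
                f"read accounting broken: {acc} != {self.n_reads_total}"
            )


@dataclass
class CountTable:
    """Genes x samples read counts plus per-sample roles and links."""

    counts: pd.DataFrame  # index genes, columns sample_ids
    samples: pd.DataFrame  # index sample_ids; columns role, cycle, replicate, biosensor

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be >= 0")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet lacks metadata for {sorted(missing)}")

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def unsorted_reference(self, sample_id: str) -> str:
        """The unsorted sample matching a sorted sample (same replicate/biosensor)."""
        meta = self.samples.loc[sample_id]
        mask = (
            (self.samples["role"] == "unsorted")
            & (self.samples["replicate"] == meta["replicate"])
            & (self.samples["biosensor"] == meta["biosensor"])
        )
        refs = self.samples.index[mask]
        if len(refs) != 1:
            raise ValueError(
                f"sample {sample_id!r} must have exactly one unsorted reference, "
                f"found {len(refs)}"
            )
        return str(refs[0])


@dataclass
class EnrichmentTable:
    """Per-gene normalized enrichments, log2 fold changes and p-values."""

    enrichment: pd.DataFrame  # index genes, columns sample_ids (NaN where undefined)
    passed_filter: pd.Series  # bool per gene
    log2fc: pd.DataFrame = field(default_factory=pd.DataFrame)  # per-cycle columns
    p_value: pd.DataFrame = field(default_factory=pd.DataFrame)  # per-cycle columns


@dataclass(frozen=True)
class CyberTConfig:
    """Cyber-T settings: prior pseudo-observations and rank-window size."""

    prior: float = 6.0
    window: int = 101

    def __post_init__(self) -> None:
        if self.prior < 0:
            raise ValueError("prior must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


# ---------------------------------------------------------------------------
# barcode extraction


def _quality_trim_3prime(quals: str, threshold: int) -> int:
    """Return the trim length under BWA-style 3' quality trimming.

    Walking from the 3' end, accumulate (threshold - q); the read is cut at the
    position maximizing the partial sum, i.e. low-quality tails are removed.
    """
    best = 0
    best_pos = len(quals)
    s = 0
    for i in range(len(quals) - 1, -1, -1):
        s += threshold - (ord(quals[i]) - 33)
        if s > best:
            best = s
            best_pos = i
    return best_pos


def _find_with_mismatches(seq: str, pattern: str, start: int, max_mm: int) -> int:
    """Leftmost start of ``pattern`` in ``seq[start:]`` allowing Hamming mismatches."""
    idx = seq.find(pattern, start)
    if idx != -1 or max_mm == 0:
        return idx
    n, m = len(seq), len(pattern)
    for i in range(start, n - m + 1):
        mm = 0
        for a, b in zip(seq[i : i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def extract_barcodes(
    fastq_path: str | Path,
    sample_id: str | None = None,
    u1: str = U1_ADAPTER,
    u2: str = U2_ADAPTER,
    min_len: int = 20,
    q_threshold: int = 20,
    max_adapter_mismatch_rate: float = 0.1,
) -> BarcodeCounts:
    """Count barcodes flanked by the U1/U2 adapters in a (gzip) FASTQ file.

    Each read is 3'-quality-trimmed at ``q_threshold``, then U1 and U2 are
    located in order (each tolerating ``floor(rate * len)`` mismatches, no
    indels).  The insert between them is reverse-complemented and counted when
    at least ``min_len`` bp long.  Reads are tallied into exactly one of:
    counted, discarded_quality (quality trimming left the read too short to
    hold both adapters plus a minimal barcode), discarded_no_adapter,
    discarded_short.
    """
    for name, ad in (("U1", u1), ("U2", u2)):
        if not ad or set(ad) - set("ACGT"):
            raise ValueError(f"{name} adapter must be non-empty ACGT")
    path = Path(fastq_path)
    out = BarcodeCounts(sample_id=sample_id or path.name)
    mm1 = int(max_adapter_mismatch_rate * len(u1))
    mm2 = int(max_adapter_mismatch_rate * len(u2))
    min_construct = len(u1) + len(u2) + min_len
    ok_qual = chr(q_threshold + 33)
    counts = out.counts
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for _title, seq, quals in FastqGeneralIterator(handle):
            out.n_reads_total += 1
            raw_len = len(seq)
            if quals and min(quals) < ok_qual:
                seq = seq[: _quality_trim_3prime(quals, q_threshold)]
            if len(seq) < min_construct <= raw_len:
                # trimming destroyed an otherwise long-enough read
                out.n_discarded_quality += 1
                continue
            i1 = _find_with_mismatches(seq, u1, 0, mm1)
            if i1 == -1:
                out.n_discarded_no_adapter += 1
                continue
            insert_start = i1 + len(u1)
            i2 = _find_with_mismatches(seq, u2, insert_start, mm2)
            if i2 == -1:
                out.n_discarded_no_adapter += 1
                continue
            insert = seq[insert_start:i2]
            if len(insert) < min_len:
                out.n_discarded_short += 1
                continue
            bc = reverse_complement(insert)
            counts[bc] = counts.get(bc, 0) + 1
    out.check_accounting()
    return out


def map_to_genes(counts: BarcodeCounts, library: LibraryMap) -> pd.Series:
    """Sum barcode counts per gene by exact 20-mer match.

    Returns a column over every gene in the map (zeros included).  Barcodes
    absent from the map increment ``counts.n_unmatched`` and credit no gene.
    """
    b2g = library.barcode_to_gene
    per_gene = dict.fromkeys(library.genes, 0)
    unmatched = 0
    for bc, n in counts.counts.items():
        gene = b2g.get(bc)
        if gene is None:
            unmatched += n
        else:
            per_gene[gene] += n
    counts.n_unmatched = unmatched
    return pd.Series(per_gene, name=counts.sample_id, dtype=np.int64)


# ---------------------------------------------------------------------------
# enrichment


def normalize_enrichment(table: CountTable) -> EnrichmentTable:
    """Per-gene enrichment of each sorted sample over its unsorted reference.

    e_{g,s} = (c_{g,s}/T_s) / (c_{g,u}/T_u): both columns are first normalized
    to their sequencing depth, then divided, cancelling library-composition
    differences.  Genes with zero unsorted reads get NaN (no pseudocounts);
    they are excluded downstream.
    """
    totals = table.totals()
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total reads: {zero}")
    freq = table.counts / totals
    enr = {}
    for sid in table.counts.columns:
        if table.samples.loc[sid, "role"] == "unsorted":
            continue
        ref = table.unsorted_reference(sid)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = freq[sid] / freq[ref].where(freq[ref] > 0)
        enr[sid] = e
    enrichment = pd.DataFrame(enr)
    passed = filter_low_reads(table)
    return EnrichmentTable(enrichment=enrichment, passed_filter=passed)


def filter_low_reads(
    table: CountTable, threshold: int = MIN_READS, mode: str = "all"
) -> pd.Series:
    """Per-gene keep-flag of the low-read filter.

    With ``mode='all'`` (default) a gene is excluded only when its raw count is
    below ``threshold`` in every sample; ``mode='any'`` excludes a gene as soon
    as one sample is below threshold.
    """
    if mode == "all":
        keep = (table.counts >= threshold).any(axis=1)
    elif mode == "any":
        keep = (table.counts >= threshold).all(axis=1)
    else:
        raise ValueError("mode must be 'all' or 'any'")
    return keep.rename("passed_filter")


def log2_fold_change(e_high, e_low):
    """log2 of high-pool over low-pool enrichment; NaN inputs propagate."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(np.asarray(e_high, float) / np.asarray(e_low, float))


# ---------------------------------------------------------------------------
# Cyber-T


def _window_mean(values: np.ndarray, w: int) -> np.ndarray:
    """Mean over the w nearest positions (full window, shifted at the edges)."""
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    half = (w - 1) // 2
    starts = np.clip(np.arange(n) - half, 0, n - w)
    return (csum[starts + w] - csum[starts]) / w


def _regularized_variance(values: np.ndarray, prior: float, w: int) -> np.ndarray:
    """Posterior variance per gene: prior-weighted blend of the gene's sample
    variance with a background estimated as the squared window-average of the
    standard deviations of the w genes nearest in rank of mean value."""
    n_rep = values.shape[1]
    s2 = values.var(axis=1, ddof=1)
    order = np.argsort(values.mean(axis=1), kind="stable")
    win_sd = np.empty(len(s2))
    win_sd[order] = _window_mean(np.sqrt(s2)[order], w)
    sigma0_sq = win_sd**2
    return (prior * sigma0_sq + (n_rep - 1) * s2) / (prior + n_rep - 2)


def cybert_test(
    values_high: pd.DataFrame | np.ndarray,
    values_low: pd.DataFrame | np.ndarray,
    cfg: CyberTConfig = CyberTConfig(),
) -> pd.Series:
    """Bayesian-regularized unpaired t-test per gene (Cyber-T).

    Inputs are genes x replicates matrices of log-scale values (one per pool).
    For each group the per-gene variance is shrunk toward a local background
    variance estimated from genes of similar mean, with ``cfg.prior``
    pseudo-observations; the t statistic uses the regularized variances and is
    referred to a t distribution with n1 + n2 - 2 + 2*prior degrees of freedom.
    """
    vh = np.asarray(values_high, dtype=float)
    vl = np.asarray(values_low, dtype=float)
    if vh.ndim != 2 or vl.ndim != 2 or vh.shape[0] != vl.shape[0]:
        raise ValueError("inputs must be genes x replicates matrices, same genes")
    nh, nl = vh.shape[1], vl.shape[1]
    if nh < 2 or nl < 2:
        raise ValueError("need >= 2 replicates per group")
    if not (np.isfinite(vh).all() and np.isfinite(vl).all()):
        raise ValueError("inputs must be finite; drop undefined genes first")
    n_genes = vh.shape[0]
    w = cfg.window
    if w > n_genes:
        w = n_genes if n_genes % 2 == 1 else n_genes - 1
        w = max(w, 1)
        warnings.warn(
            f"window {cfg.window} exceeds gene count {n_genes}; shrunk to {w}",
            stacklevel=2,
        )
    st2_h = _regularized_variance(vh, cfg.prior, w)
    st2_l = _regularized_variance(vl, cfg.prior, w)
    diff = vh.mean(axis=1) - vl.mean(axis=1)
    denom = np.sqrt(st2_h / nh + st2_l / nl)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.where((denom == 0) & (diff == 0), 0.0, t)
    df = nh + nl - 2 + 2 * cfg.prior
    p = 2.0 * stats.t.sf(np.abs(t), df)
    index = (
        values_high.index
        if isinstance(values_high, pd.DataFrame)
        else pd.RangeIndex(n_genes)
    )
    return pd.Series(p, index=index, name="p_value")


# ---------------------------------------------------------------------------
# screen analysis


def analyze_screen(
    table: CountTable,
    cfg: CyberTConfig = CyberTConfig(),
    read_threshold: int = MIN_READS,
    filter_mode: str = "all",
) -> EnrichmentTable:
    """Full enrichment analysis of a sorted-library count table.

    For every sorting cycle present, per-replicate enrichments of the high and
    low pools are computed against their unsorted references; the reported
    log2 fold change is the mean over replicates of log2(e_high/e_low) and the
    p-value comes from the Cyber-T test on the per-replicate log2 enrichments.
    Genes failing the read filter, or with undefined enrichment in any pool of
    a cycle, get NaN for that cycle.
    """
    et = normalize_enrichment(table)
    et.passed_filter = filter_low_reads(table, read_threshold, filter_mode)
    cycles = sorted(
        {
            int(c)
            for c in table.samples.loc[
                table.samples["role"].isin(["high_sorted", "low_sorted"]), "cycle"
            ]
        }
    )
    log2fc, pvals = {}, {}
    for cyc in cycles:
        meta = table.samples
        high = meta.index[(meta["role"] == "high_sorted") & (meta["cycle"] == cyc)]
        low = meta.index[(meta["role"] == "low_sorted") & (meta["cycle"] == cyc)]
        if len(high) == 0 or len(low) == 0:
            continue
        eh = np.log2(et.enrichment[list(high)].where(et.enrichment[list(high)] > 0))
        el = np.log2(et.enrichment[list(low)].where(et.enrichment[list(low)] > 0))
        usable = (
            et.passed_filter
            & eh.notna().all(axis=1)
            & el.notna().all(axis=1)
        )
        fc = pd.Series(np.nan, index=et.enrichment.index)
        fc[usable] = eh[usable].mean(axis=1).values - el[usable].mean(axis=1).values
        log2fc[f"log2FC_x{cyc}"] = fc
        p = pd.Series(np.nan, index=et.enrichment.index)
        if usable.any() and len(high) >= 2 and len(low) >= 2:
            p[usable] = cybert_test(eh[usable], el[usable], cfg).values
        pvals[f"p_x{cyc}"] = p
    et.log2fc = pd.DataFrame(log2fc)
    et.p_value = pd.DataFrame(pvals)
    return et


def enrichment_report(
    table: EnrichmentTable,
    fc_threshold: float,
    p_threshold: float = 0.05,
    cycle: int | None = None,
    direction: str = "both",
) -> pd.DataFrame:
    """Ranked hit list: genes passing |log2FC| and p thresholds on one cycle.

    Genes failing the read filter are never reported.  The report carries all
    cycles' log2FC/p columns side by side and is sorted by the primary cycle's
    log2FC, descending for high-pool hits (``direction='high'`` keeps positive
    fold changes only, ``'low'`` negative only, ``'both'`` keeps either sign).
    """
    if table.log2fc.empty:
        raise ValueError("enrichment table has no fold-change columns")
    cycles = sorted(int(c.split("_x")[1]) for c in table.log2fc.columns)
    cyc = cycle if cycle is not None else cycles[0]
    fc = table.log2fc[f"log2FC_x{cyc}"]
    p = table.p_value[f"p_x{cyc}"]
    keep = table.passed_filter & (fc.abs() > fc_threshold) & (p <= p_threshold)
    if direction == "high":
        keep &= fc > 0
    elif direction == "low":
        keep &= fc < 0
    elif direction != "both":
        raise ValueError("direction must be 'high', 'low' or 'both'")
    report = pd.concat([table.log2fc, table.p_value], axis=1)[keep.fillna(False)]
    report = report.sort_values(
        f"log2FC_x{cyc}", ascending=(direction == "low"), key=lambda s: s
    )
    report.index.name = "gene"
    return report.reset_index()
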