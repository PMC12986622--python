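"""Genotype containers, VCF/TSV I/O, variant QC, LD pruning and panel merging.

Dosages are stored as a ``float64`` sample × variant matrix with values in
{0, 1, 2} and ``NaN`` for missing calls — the additive coding of a biallelic
SNP counting copies of the alternate allele. All quality-control steps
operate on this container; mean-centering for the prediction models is done
downstream and never stored here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix", "FilterReport", "MergeReport", "VcfParseError",
    "read_vcf", "write_vcf", "read_dosage_tsv", "write_dosage_tsv",
    "filter_variants", "ld_prune", "impute_missing", "merge_panels",
]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
_BASES = frozenset("ACGT")
# ref/alt pairs that are their own reverse complement; a swapped match may be
# a strand flip rather than an allele swap, so these are dropped on merge
_AMBIGUOUS_PAIRS = frozenset({frozenset(("A", "T")), frozenset(("C", "G"))})


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be decoded into dosages."""


@dataclass
class GenotypeMatrix:
    """Accession × SNP dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids
        Ordered, unique accession identifiers (rows).
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` (columns of the
        dosage matrix, in order). ``pos`` is 1-based. Multi-allelic records
        carry a comma-joined ``alt`` and survive parsing; they are removed
        by the biallelic filter.
    dosages
        ``(n_samples, n_variants)`` float array, entries in {0, 1, 2} or NaN.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table missing columns {sorted(missing_cols)}")
        keys = list(zip(self.variants["chrom"], self.variants["pos"],
                        self.variants["ref"], self.variants["alt"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos, ref, alt) variant records")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[tuple]:
        """(chrom, pos, ref, alt) tuples in column order."""
        return list(zip(self.variants["chrom"], self.variants["pos"],
                        self.variants["ref"], self.variants["alt"]))

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls.

        Variants with no non-missing call get NaN.
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant (allele-label invariant)."""
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def is_biallelic_snp(self) -> np.ndarray:
        """True where ref and alt are both single A/C/G/T alleles."""
        ref = self.variants["ref"].astype(str)
        alt = self.variants["alt"].astype(str)
        ok = (ref.str.len() == 1) & (alt.str.len() == 1)
        ok &= ref.isin(_BASES) & alt.isin(_BASES)
        return ok.to_numpy()

    def take_variants(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(self.sample_ids,
                              self.variants.iloc[index],
                              self.dosages[:, index])

    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix([self.sample_ids[i] for i in index],
                              self.variants,
                              self.dosages[index, :])

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"sample ids not in matrix: {missing[:5]}")
        return self.take_samples([pos[s] for s in ids])


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_variants` — every removal counted once."""

    n_input: int
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_removed_multiallelic: int = 0
    n_removed_ld: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        removals = (self.n_removed_missing + self.n_removed_maf
                    + self.n_removed_multiallelic + self.n_removed_ld)
        if self.n_retained != self.n_input - removals:
            raise ValueError("filter report does not balance")
        if min(self.n_input, self.n_removed_missing, self.n_removed_maf,
               self.n_removed_multiallelic, self.n_removed_ld,
               self.n_retained) < 0:
            raise ValueError("negative count in filter report")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class MergeReport:
    """Variant accounting for :func:`merge_panels`."""

    n_matched: int = 0            # exact (ref, alt) matches kept as-is
    n_flipped: int = 0            # allele-swapped matches kept with 2 - x
    n_dropped_ambiguous: int = 0  # A/T or C/G swapped pairs
    n_dropped_mismatch: int = 0   # shared position, irreconcilable alleles
    n_only_a: int = 0
    n_only_b: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_matched + self.n_flipped

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["n_retained"] = self.n_retained
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF (4.x, GT field) into a :class:`GenotypeMatrix`.

    Diploid GT pairs map to alternate-allele dosage: 0/0 → 0, 0/1 or 1/0 → 1,
    1/1 → 2, any missing allele → NaN. Phase is ignored. Multi-allelic
    records are retained (alt alleles comma-joined) and left for the
    biallelic filter; their dosage counts any non-reference allele.

    Raises
    ------
    VcfParseError
        On an undecodable record (with its 1-based record number) or a
        non-diploid genotype.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    recno = 0
    try:
        for recno, rec in enumerate(vcf, start=1):
            alts = rec.ALT if rec.ALT else ["."]
            rows.append((rec.CHROM, rec.POS, rec.ID or ".", rec.REF,
                         ",".join(alts)))
            col = np.empty(len(samples))
            for si, gt in enumerate(rec.genotypes):
                alleles = gt[:-1]  # last entry is the phase flag
                if len(alleles) != 2:
                    raise VcfParseError(
                        f"non-diploid genotype for sample {samples[si]!r} "
                        f"at record {recno} ({rec.CHROM}:{rec.POS})")
                if min(alleles) < 0:
                    col[si] = np.nan
                else:
                    col[si] = sum(a != 0 for a in alleles)
            dosage_cols.append(col)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record {recno + 1}: {exc}") from exc
    finally:
        vcf.close()
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (np.column_stack(dosage_cols) if dosage_cols
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples, variants, dosages)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 (GT only, unphased, 1-based positions)."""
    _GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(G.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j, v in G.variants.iterrows():
            gts = [("./." if np.isnan(d) else _GT[d]) for d in G.dosages[:, j]]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def write_dosage_tsv(G: GenotypeMatrix, path: str) -> None:
    """Write a variant × sample dosage TSV (metadata columns first, NA missing)."""
    dosage_df = pd.DataFrame(G.dosages.T, columns=G.sample_ids)
    df = pd.concat([G.variants.reset_index(drop=True), dosage_df], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    return GenotypeMatrix(samples, df[VARIANT_COLUMNS],
                          df[samples].to_numpy(dtype=float).T)


# ---------------------------------------------------------------------------
# QC


def filter_variants(G: GenotypeMatrix, max_missing_rate: float = 0.20,
                    min_maf: float = 0.05) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the standard variant filters in the order biallelic → missing → MAF.

    Removes (1) records that are not biallelic SNPs, (2) variants whose
    missing-call fraction exceeds ``max_missing_rate`` (an all-missing
    variant is always removed here), and (3) variants whose minor allele
    frequency over non-missing calls is below ``min_maf``. Each removal is
    attributed to exactly one filter. An empty matrix in or out is legal.
    """
    if not 0 <= max_missing_rate <= 1:
        raise ValueError("max_missing_rate must be in [0, 1]")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    n_input = G.n_variants
    biallelic = G.is_biallelic_snp()
    n_multi = int((~biallelic).sum())

    miss = G.missing_fraction()
    all_missing = miss >= 1.0
    pass_missing = biallelic & (miss <= max_missing_rate) & ~all_missing
    n_missing = int((biallelic & ~pass_missing).sum())

    maf = G.maf()
    with np.errstate(invalid="ignore"):
        pass_maf = pass_missing & (maf >= min_maf)
    n_maf = int((pass_missing & ~pass_maf).sum())

    keep = np.flatnonzero(pass_maf)
    report = FilterReport(n_input=n_input, n_removed_multiallelic=n_multi,
                          n_removed_missing=n_missing, n_removed_maf=n_maf,
                          n_retained=len(keep))
    return G.take_variants(keep), report


def _window_r2(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation, pairwise-complete over NaN."""
    df = pd.DataFrame(dosages)
    r = df.corr(min_periods=2).to_numpy()
    return np.nan_to_num(r, nan=0.0) ** 2


def ld_prune(G: GenotypeMatrix, window_snps: int = 52, step_snps: int = 10,
             r2_threshold: float = 0.5) -> tuple[np.ndarray, FilterReport]:
    """Greedy windowed LD pruning per chromosome (variant-count windows).

    Within each window of ``window_snps`` consecutive variants, while any
    surviving pair has squared dosage correlation strictly above
    ``r2_threshold``, the worst (highest-r²) pair is found and one member is
    removed — the one with lower MAF, ties broken by removing the later
    position. The window then slides by ``step_snps``. Returns the kept
    variant indices (strictly increasing, into ``G``'s columns) and a
    :class:`FilterReport` attributing removals to the LD filter.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps >= window_snps:
        raise ValueError("step_snps must be smaller than window_snps")
    n = G.n_variants
    removed = np.zeros(n, dtype=bool)
    maf = G.maf()
    pos = G.variants["pos"].to_numpy()
    chrom = G.variants["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            window = idx[start:start + window_snps]
            active = [i for i in window if not removed[i]]
            while len(active) > 1:
                r2 = _window_r2(G.dosages[:, active])
                np.fill_diagonal(r2, 0.0)
                worst = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[worst] <= r2_threshold:
                    break
                a, b = active[worst[0]], active[worst[1]]
                if (maf[a], -pos[a]) < (maf[b], -pos[b]):
                    drop = a
                elif (maf[b], -pos[b]) < (maf[a], -pos[a]):
                    drop = b
                else:  # identical MAF and position cannot happen; later wins
                    drop = max(a, b)
                removed[drop] = True
                active.remove(drop)
            start += step_snps
    kept = np.flatnonzero(~removed)
    report = FilterReport(n_input=n, n_removed_ld=int(removed.sum()),
                          n_retained=len(kept))
    return kept, report


def impute_missing(G: GenotypeMatrix,
                   method: str = "column_mean_rounded") -> GenotypeMatrix:
    """Fill missing dosages one variant at a time.

    ``column_mean_rounded`` replaces missing calls with the non-missing
    column mean rounded to the nearest of {0, 1, 2}, ties toward 1.
    ``column_mode`` uses the most frequent non-missing dosage (ties resolved
    toward the value nearest 1, then the smaller). Every variant must have
    at least one non-missing call — filter first otherwise.
    """
    if method not in ("column_mean_rounded", "column_mode"):
        raise ValueError(f"unknown imputation method {method!r}")
    miss = np.isnan(G.dosages)
    if not miss.any():
        return G
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = np.flatnonzero(all_missing)[:5]
        raise ValueError(
            f"variants with all calls missing (e.g. columns {bad.tolist()}); "
            "apply filter_variants before imputation")
    dosages = G.dosages.copy()
    for j in np.flatnonzero(miss.any(axis=0)):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        if method == "column_mean_rounded":
            mean = obs.mean()
            # nearest of {0,1,2}; on a tie prefer the heterozygote
            fill = min((0.0, 1.0, 2.0), key=lambda v: (abs(v - mean), v != 1.0))
        else:
            counts = {v: int((obs == v).sum()) for v in (0.0, 1.0, 2.0)}
            fill = max((0.0, 1.0, 2.0),
                       key=lambda v: (counts[v], -abs(v - 1.0), -v))
        col[np.isnan(col)] = fill
    return GenotypeMatrix(G.sample_ids, G.variants, dosages)


def merge_panels(G_a: GenotypeMatrix,
                 G_b: GenotypeMatrix) -> tuple[GenotypeMatrix, MergeReport]:
    """Merge two panels on shared (chrom, pos) variants.

    Exact (ref, alt) matches are kept as-is; allele-swapped matches
    (ref_a = alt_b and alt_a = ref_b) are kept with panel-b dosages flipped
    to ``2 - x`` — except strand-ambiguous A/T and C/G pairs, which are
    dropped, as are all other allele mismatches and positions duplicated
    within a panel. The output holds all samples of both panels (a first)
    over the surviving intersection, in panel-a variant order.
    """
    overlap = set(G_a.sample_ids) & set(G_b.sample_ids)
    if overlap:
        raise ValueError(f"duplicate sample ids across panels: "
                         f"{sorted(overlap)[:5]}")

    def position_map(G):
        m: dict[tuple, int | None] = {}
        for j, (c, p) in enumerate(zip(G.variants["chrom"], G.variants["pos"])):
            m[(c, p)] = None if (c, p) in m else j  # None marks a duplicate
        return m

    map_a, map_b = position_map(G_a), position_map(G_b)
    report = MergeReport()
    keep_a, keep_b, flip = [], [], []
    for (c, p), ja in map_a.items():
        if (c, p) not in map_b:
            report.n_only_a += 1
            continue
        jb = map_b[(c, p)]
        if ja is None or jb is None:  # position duplicated within a panel
            report.n_dropped_mismatch += 1
            continue
        ra, aa = G_a.variants.loc[ja, ["ref", "alt"]]
        rb, ab = G_b.variants.loc[jb, ["ref", "alt"]]
        if (ra, aa) == (rb, ab):
            report.n_matched += 1
            keep_a.append(ja); keep_b.append(jb); flip.append(False)
        elif (ra, aa) == (ab, rb):
            if frozenset((ra, aa)) in _AMBIGUOUS_PAIRS:
                report.n_dropped_ambiguous += 1
            else:
                report.n_flipped += 1
                keep_a.append(ja); keep_b.append(jb); flip.append(True)
        else:
            report.n_dropped_mismatch += 1
    report.n_only_b = sum(1 for key in map_b if key not in map_a)

    dos_b = G_b.dosages[:, keep_b].copy()
    flip = np.asarray(flip, dtype=bool)
    if flip.any():
        dos_b[:, flip] = 2.0 - dos_b[:, flip]
    merged = GenotypeMatrix(
        list(G_a.sample_ids) + list(G_b.sample_ids),
        G_a.variants.iloc[keep_a],
        np.vstack([G_a.dosages[:, keep_a], dos_b]))
    return merged, report
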