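"""Genotype I/O, variant QC and LD pruning.

Genotypes are held as an additive-coded samples x variants matrix (0/1/2
copies of the alternate allele, ``MISSING`` = -1 for no-calls) together with
per-variant metadata.  Supported on-disk dialects: VCF (GT field), PLINK
text ``.ped``/``.map``, PLINK additive-recode ``.raw`` and a plain TSV with a
header row of variant IDs, a first column of sample IDs and ``NA`` for
missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

Format = Literal["vcf", "plink_ped", "plink_raw", "tsv"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not parse under the named dialect."""


@dataclass(frozen=True)
class VariantRecord:
    """Metadata for one biallelic SNP.

    ``call_rate`` and ``maf`` are computed from the non-missing calls of the
    matrix the record belongs to; ``maf`` is folded (never above 0.5).
    """

    id: str
    chromosome: str = "0"
    position: int = 0
    alleles: tuple[str, str] = ("A", "B")
    call_rate: float = 1.0
    maf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"call_rate {self.call_rate} outside [0,1]")
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError(f"maf {self.maf} outside [0,0.5]")


@dataclass
class GenotypeMatrix:
    """Samples x variants additive genotype matrix.

    Attributes
    ----------
    samples
        Ordered, unique sample identifiers.
    variants
        Ordered :class:`VariantRecord` with unique IDs.
    calls
        ``int8`` array of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2, MISSING}`` counting alternate (A1) alleles.
    phenotype
        Optional per-sample label in ``{"case", "control", "unknown"}``.
    """

    samples: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray
    phenotype: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant IDs")
        if self.phenotype is not None and len(self.phenotype) != len(self.samples):
            raise ValueError("phenotype length != n_samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in keep],
            calls=self.calls[:, keep].copy(),
            phenotype=None if self.phenotype is None else list(self.phenotype),
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            variants=list(self.variants),
            calls=self.calls[keep, :].copy(),
            phenotype=None
            if self.phenotype is None
            else [self.phenotype[i] for i in keep],
        )


def _variant_stats(column: np.ndarray) -> tuple[float, float]:
    """(call_rate, folded maf) from one additive-coded column."""
    called = column != MISSING
    n = column.size
    call_rate = float(called.sum()) / n if n else 0.0
    if called.sum() == 0:
        return call_rate, 0.0
    p_alt = float(column[called].sum()) / (2.0 * called.sum())
    return call_rate, min(p_alt, 1.0 - p_alt)


def annotate_stats(g: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy with per-variant ``call_rate`` and ``maf`` recomputed."""
    variants = []
    for j, v in enumerate(g.variants):
        cr, maf = _variant_stats(g.calls[:, j])
        variants.append(replace(v, call_rate=cr, maf=maf))
    return GenotypeMatrix(list(g.samples), variants, g.calls.copy(),
                          None if g.phenotype is None else list(g.phenotype))


def make_genotype_matrix(
    samples: Sequence[str],
    variants: Sequence[VariantRecord],
    calls: np.ndarray,
    phenotype: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Build a :class:`GenotypeMatrix` with stats computed from the calls."""
    g = GenotypeMatrix(list(samples), list(variants), calls,
                       None if phenotype is None else list(phenotype))
    return annotate_stats(g)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: Format) -> GenotypeMatrix:
    """Read genotypes from ``path`` under the named dialect.

    Additive coding counts the alternate (VCF ALT / PLINK A1) allele.
    Non-biallelic VCF records are skipped with a warning.  Per-variant
    ``call_rate`` and ``maf`` are computed from the non-missing calls.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_ped":
        return _read_ped(path)
    if format == "plink_raw":
        return _read_raw(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"{path}: not parseable as TSV: {exc}") from exc
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    arr = df.to_numpy()
    for (i, j), val in np.ndenumerate(arr):
        if isinstance(val, str):
            val = val.strip()
        if val in ("NA", "", None) or (isinstance(val, float) and np.isnan(val)):
            continue
        try:
            code = int(val)
        except (TypeError, ValueError):
            raise GenotypeParseError(
                f"{path}: line {i + 2}: bad genotype {val!r}") from None
        if code not in (0, 1, 2):
            raise GenotypeParseError(f"{path}: line {i + 2}: bad genotype {code}")
        calls[i, j] = code
    variants = [VariantRecord(id=str(c)) for c in df.columns]
    return make_genotype_matrix([str(s) for s in df.index], variants, calls)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNP record %s:%s",
                           rec.CHROM, rec.POS)
            continue
        # gts012: 0/1/2 alt-allele dosage, 3 = missing
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantRecord(id=vid, chromosome=str(rec.CHROM),
                                      position=int(rec.POS),
                                      alleles=(rec.REF, rec.ALT[0])))
        columns.append(gt)
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0), dtype=np.int8))
    return make_genotype_matrix(samples, variants, calls)


def _read_ped(path: Path) -> GenotypeMatrix:
    """PLINK text pedigree; ``path`` is the .ped, the .map sits beside it."""
    map_path = path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(map_path)
    variants_meta = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path}: line {ln}: expected "
                                         f"4 columns, got {len(parts)}")
            chrom, vid, _cm, pos = parts[:4]
            variants_meta.append((vid, chrom, int(pos)))
    n_var = len(variants_meta)
    samples: list[str] = []
    phenotypes: list[str] = []
    rows: list[np.ndarray] = []
    allele_pairs: list[dict[str, int]] = [dict() for _ in range(n_var)]
    raw_rows: list[list[tuple[str, str]]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise GenotypeParseError(
                    f"{path}: line {ln}: expected {6 + 2 * n_var} fields, "
                    f"got {len(parts)}")
            samples.append(parts[1])
            phenotypes.append({"1": "control", "2": "case"}.get(parts[5], "unknown"))
            pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_var)]
            raw_rows.append(pairs)
            for j, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0":
                        allele_pairs[j][al] = allele_pairs[j].get(al, 0) + 1
    # A1 = minor (least common) allele, as PLINK does; count A1 copies.
    variants: list[VariantRecord] = []
    a1_list: list[str] = []
    for j, (vid, chrom, pos) in enumerate(variants_meta):
        counts = allele_pairs[j]
        if len(counts) > 2:
            raise GenotypeParseError(f"{path}: variant {vid} has "
                                     f"{len(counts)} alleles")
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        if not alleles:
            alleles = ["A", "B"]
        if len(alleles) == 1:
            alleles = ["?", alleles[0]] if alleles[0] != "?" else ["!", alleles[0]]
        a1, a2 = alleles[0], alleles[-1]
        a1_list.append(a1)
        variants.append(VariantRecord(id=vid, chromosome=chrom, position=pos,
                                      alleles=(a2, a1)))
    calls = np.full((len(samples), n_var), MISSING, dtype=np.int8)
    for i, pairs in enumerate(raw_rows):
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            calls[i, j] = (a == a1_list[j]) + (b == a1_list[j])
    g = make_genotype_matrix(samples, variants, calls, phenotypes)
    return g


def _read_raw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != required:
        raise GenotypeParseError(f"{path}: header must start with {required}")
    snp_cols = list(df.columns[6:])
    calls = np.full((len(df), len(snp_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(snp_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = vals.notna()
        calls[ok.to_numpy(), j] = vals[ok].astype(int).to_numpy()
    variants = []
    for col in snp_cols:
        # .raw columns are "<snp>_<counted allele>"
        vid, _, a1 = col.rpartition("_")
        if not vid:
            vid, a1 = col, "A"
        variants.append(VariantRecord(id=vid, alleles=("?", a1)))
    pheno = [{"1": "control", "2": "case"}.get(str(int(p)) if p == p else "",
                                              "unknown")
             for p in pd.to_numeric(df["PHENOTYPE"], errors="coerce")]
    return make_genotype_matrix(df["IID"].astype(str).tolist(), variants,
                                calls, pheno)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path: str | Path, format: Format) -> None:
    """Write ``g`` to ``path`` in the named dialect (inverse of the reader)."""
    path = Path(path)
    if format == "tsv":
        _write_tsv(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    elif format == "plink_ped":
        _write_ped(g, path)
    elif format == "plink_raw":
        _write_raw(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_tsv(g: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(
        np.where(g.calls == MISSING, None, g.calls),
        index=g.samples, columns=g.variant_ids(),
    )
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for v in g.variants:
            c = v.chromosome if v.chromosome != "0" else "1"
            if c not in chroms:
                chroms.append(c)
        for c in chroms or ["1"]:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j, v in enumerate(g.variants):
            chrom = v.chromosome if v.chromosome != "0" else "1"
            pos = v.position if v.position > 0 else j + 1
            ref, alt = v.alleles
            row = [chrom, str(pos), v.id, ref or "A", alt or "C", ".", ".",
                   ".", "GT"]
            row += [gt_map[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def _write_ped(g: GenotypeMatrix, path: Path) -> None:
    map_path = path.with_suffix(".map")
    with open(map_path, "w") as fh:
        for j, v in enumerate(g.variants):
            chrom = v.chromosome if v.chromosome != "0" else "1"
            pos = v.position if v.position > 0 else j + 1
            fh.write(f"{chrom}\t{v.id}\t0\t{pos}\n")
    pheno_code = {"control": "1", "case": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for i, sid in enumerate(g.samples):
            ph = pheno_code[g.phenotype[i]] if g.phenotype else "0"
            fields = [sid, sid, "0", "0", "0", ph]
            for j, v in enumerate(g.variants):
                ref, alt = v.alleles
                c = int(g.calls[i, j])
                pair = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt),
                        MISSING: ("0", "0")}[c]
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def _write_raw(g: GenotypeMatrix, path: Path) -> None:
    pheno_code = {"control": "1", "case": "2", "unknown": "-9"}
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    header += [f"{v.id}_{v.alleles[1]}" for v in g.variants]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(g.samples):
            ph = pheno_code[g.phenotype[i]] if g.phenotype else "-9"
            fields = [sid, sid, "0", "0", "0", ph]
            fields += ["NA" if c == MISSING else str(int(c))
                       for c in g.calls[i, :]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_variants(
    g: GenotypeMatrix, min_call_rate: float = 0.95, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Keep variants with ``call_rate > min_call_rate`` and ``maf > min_maf``.

    Strict inequalities, matching the usual "call rate greater than 95% and
    minor allele frequency greater than 5%" phrasing.  The sample set is
    unchanged; raises if no variant survives.
    """
    for t in (min_call_rate, min_maf):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0,1]")
    g = annotate_stats(g)
    keep = [j for j, v in enumerate(g.variants)
            if v.call_rate > min_call_rate and v.maf > min_maf]
    if not keep:
        raise ValueError(
            "all variants removed by QC filters; review min_call_rate/min_maf")
    return g.subset_variants(keep)


def filter_samples(g: GenotypeMatrix, min_call_rate: float = 0.93) -> GenotypeMatrix:
    """Optional sample-level QC: drop samples with call rate <= threshold."""
    called = (g.calls != MISSING).mean(axis=1)
    keep = [i for i in range(g.n_samples) if called[i] > min_call_rate]
    if not keep:
        raise ValueError("all samples removed by call-rate filter")
    return g.subset_samples(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete observations."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def ld_prune(
    g: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.30
) -> GenotypeMatrix:
    """Sliding-window LD pruning on squared genotype correlation.

    Within each window of ``window`` SNPs (per chromosome, position order),
    every pair with r² > ``r2_max`` has its later-positioned member removed;
    windows then advance by ``step`` SNPs.  Original variant order is
    preserved in the output.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 1 <= step < window:
        raise ValueError("step must satisfy 1 <= step < window")
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0,1)")
    for v in g.variants:
        if v.position <= 0:
            raise ValueError(f"variant {v.id} lacks coordinates; "
                             "LD pruning requires chromosome/position")
    removed: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for j, v in enumerate(g.variants):
        by_chrom.setdefault(v.chromosome, []).append(j)
    for chrom, idx in by_chrom.items():
        idx = sorted(idx, key=lambda j: g.variants[j].position)
        start = 0
        while True:
            win = idx[start:start + window]
            if len(win) >= 2:
                for a_pos in range(len(win)):
                    ja = win[a_pos]
                    if ja in removed:
                        continue
                    for b_pos in range(a_pos + 1, len(win)):
                        jb = win[b_pos]
                        if jb in removed:
                            continue
                        r2 = _pairwise_r2(g.calls[:, ja], g.calls[:, jb])
                        if r2 > r2_max:
                            removed.add(jb)  # drop the later SNP
            if start + window >= len(idx):
                break
            start += step
    keep = [j for j in range(g.n_variants) if j not in removed]
    logger.info("ld_prune: removed %d of %d variants", len(removed), g.n_variants)
    return g.subset_variants(keep)


# ---------------------------------------------------------------------------
# Sidecar tables
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, value) -> dict, e.g. clusters/phenotypes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: expected two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: dict[str, str], path: str | Path,
                 value_name: str = "value") -> None:
    pd.DataFrame({"sample_id": list(labels), value_name: list(labels.values())}
                 ).to_csv(path, sep="\t", index=False)
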