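"""Core data containers and TSV input/output for GWAS summary statistics.

A study contributes a table of per-SNP association p-values; a separate
annotation table supplies chromosome, base-pair position and minor allele
frequency (MAF).  Studies are merged by SNP identifier into a complete
SNP x study p-value matrix (inner join: a SNP is kept only if present in
every study and in the annotation), the shape the rank-product machinery
requires.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MergeError, SchemaError

log = logging.getLogger(__name__)

#: logical -> actual header names of the minimal dialect
MINIMAL_COLUMNS = {"snp_id": "snp_id", "p": "p"}
#: logical -> actual header names of the PLINK .assoc dialect
PLINK_COLUMNS = {"snp_id": "SNP", "chromosome": "CHR", "position": "BP", "p": "P"}


def _norm_chrom(label: object) -> str:
    """Normalise a chromosome label: strip whitespace and a leading 'chr'.

    Applied identically to every file so labels compare as opaque strings.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass(frozen=True)
class SnpAnnotation:
    """Positional and allele-frequency annotation for one SNP.

    ``position`` is a 1-based base-pair coordinate; ``maf`` is the minor
    allele frequency, in (0, 0.5].
    """

    snp_id: str
    chromosome: str
    position: int
    maf: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SchemaError(f"{self.snp_id}: position must be >= 1, got {self.position}")
        if not (0.0 < self.maf <= 0.5):
            raise SchemaError(f"{self.snp_id}: MAF must lie in (0, 0.5], got {self.maf}")


@dataclass
class StudySummary:
    """One study's SNP -> p-value map.

    ``n_skipped`` counts input rows dropped because p was non-numeric or
    outside (0, 1]; p = 0 in particular is excluded because log p (and hence
    the Fisher statistic) would be undefined.
    """

    study_id: str
    snp_ids: list[str]
    pvalues: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if len(self.snp_ids) != self.pvalues.size:
            raise SchemaError(f"{self.study_id}: {len(self.snp_ids)} ids vs {self.pvalues.size} p-values")
        if self.pvalues.size and not ((self.pvalues > 0) & (self.pvalues <= 1)).all():
            bad = self.pvalues[~((self.pvalues > 0) & (self.pvalues <= 1))][0]
            raise SchemaError(f"{self.study_id}: p-value outside (0, 1]: {bad}")
        seen: set[str] = set()
        for sid in self.snp_ids:
            if sid in seen:
                raise SchemaError(f"{self.study_id}: duplicate snp_id {sid!r}")
            seen.add(sid)

    @property
    def records(self) -> list[tuple[str, float]]:
        return list(zip(self.snp_ids, self.pvalues.tolist()))

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class MergedDataset:
    """Inner-joined SNP x study p-value matrix with per-SNP annotation.

    Rows are sorted by (chromosome, position, snp_id) so the layout is
    reproducible regardless of input order.  ``drop_counts`` records, per
    source, how many SNPs fell out of the intersection.
    """

    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    mafs: np.ndarray
    pmatrix: np.ndarray
    study_ids: list[str]
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.pmatrix = np.asarray(self.pmatrix, dtype=float)
        n = self.snp_ids.size
        if self.pmatrix.shape != (n, len(self.study_ids)):
            raise MergeError(
                f"pmatrix shape {self.pmatrix.shape} does not match "
                f"{n} SNPs x {len(self.study_ids)} studies"
            )
        if n and np.isnan(self.pmatrix).any():
            raise MergeError("pmatrix contains missing cells; merge must be complete")

    @property
    def n_snps(self) -> int:
        return int(self.snp_ids.size)

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)


def read_summary_table(
    path,
    column_map: dict[str, str] | None = None,
    study_id: str | None = None,
) -> StudySummary:
    """Read one study's summary table (TSV with a header row).

    ``column_map`` maps the logical names ``snp_id`` and ``p`` to the file's
    actual headers.  When omitted, the minimal dialect (``snp_id``, ``p``)
    and the PLINK .assoc dialect (``SNP``, ``P``) are auto-detected.  Rows
    whose p-value is non-numeric or outside (0, 1] are dropped and tallied
    in ``n_skipped``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map is None:
        if set(MINIMAL_COLUMNS.values()) <= set(df.columns):
            column_map = MINIMAL_COLUMNS
        elif {PLINK_COLUMNS["snp_id"], PLINK_COLUMNS["p"]} <= set(df.columns):
            column_map = PLINK_COLUMNS
        else:
            raise SchemaError(
                f"{path}: cannot find SNP-identifier and p-value columns "
                f"(headers: {list(df.columns)}); pass column_map"
            )
    for logical in ("snp_id", "p"):
        actual = column_map.get(logical, logical)
        if actual not in df.columns:
            raise SchemaError(f"{path}: required column {actual!r} (for {logical!r}) is missing")
    ids = df[column_map.get("snp_id", "snp_id")].astype(str)
    p = pd.to_numeric(df[column_map.get("p", "p")], errors="coerce")
    keep = p.notna() & (p > 0) & (p <= 1)
    n_skipped = int((~keep).sum())
    if n_skipped:
        log.warning("%s: dropped %d rows with missing or out-of-range p-values", path, n_skipped)
    ids_kept = ids[keep]
    dup = ids_kept[ids_kept.duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicate snp_id {dup.iloc[0]!r}")
    label = study_id if study_id is not None else _stem(path)
    return StudySummary(
        study_id=label,
        snp_ids=ids_kept.tolist(),
        pvalues=p[keep].to_numpy(dtype=float),
        n_skipped=n_skipped,
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def read_annotation(path) -> list[SnpAnnotation]:
    """Read SNP annotation (TSV: snp_id, chromosome, position, maf).

    MAF values in (0.5, 1) are folded to ``1 - maf`` (major-allele
    convention in some annotation dialects) with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "chromosome", "position", "maf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: annotation is missing column(s) {missing}")
    out: list[SnpAnnotation] = []
    n_folded = 0
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(float(row.position))
            maf = float(row.maf)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}:{line}: unparseable position/maf ({exc})") from None
        if math.isnan(maf):
            raise SchemaError(f"{path}:{line}: unparseable maf")
        if 0.5 < maf < 1.0:
            maf = 1.0 - maf
            n_folded += 1
        try:
            out.append(SnpAnnotation(str(row.snp_id), _norm_chrom(row.chromosome), pos, maf))
        except SchemaError as exc:
            raise SchemaError(f"{path}:{line}: {exc}") from None
    if n_folded:
        log.warning("%s: folded %d MAF values > 0.5 to the minor-allele convention", path, n_folded)
    return out


def merge_studies(studies: list[StudySummary], annotation: list[SnpAnnotation]) -> MergedDataset:
    """Inner-join >= 2 studies with the annotation by SNP identifier.

    Only SNPs present in every study AND the annotation survive; per-source
    drop counts are recorded.  Raises if the intersection is empty.
    """
    if len(studies) < 2:
        raise MergeError(f"need at least 2 studies to merge, got {len(studies)}")
    ann_by_id = {a.snp_id: a for a in annotation}
    common = set(ann_by_id)
    for s in studies:
        common &= set(s.snp_ids)
    if not common:
        sizes = {s.study_id: len(s) for s in studies}
        sizes["annotation"] = len(annotation)
        raise MergeError(f"no SNP is present in every source; per-source sizes: {sizes}")
    drop_counts = {s.study_id: len(s) - len(common) for s in studies}
    drop_counts["annotation"] = len(annotation) - len(common)

    kept = sorted(common, key=lambda sid: (ann_by_id[sid].chromosome, ann_by_id[sid].position, sid))
    index = {sid: i for i, sid in enumerate(kept)}
    n, k = len(kept), len(studies)
    pmat = np.full((n, k), np.nan)
    for j, s in enumerate(studies):
        for sid, p in zip(s.snp_ids, s.pvalues):
            i = index.get(sid)
            if i is not None:
                pmat[i, j] = p
    return MergedDataset(
        snp_ids=np.array(kept, dtype=object),
        chromosomes=np.array([ann_by_id[s].chromosome for s in kept], dtype=object),
        positions=np.array([ann_by_id[s].position for s in kept], dtype=np.int64),
        mafs=np.array([ann_by_id[s].maf for s in kept], dtype=float),
        pmatrix=pmat,
        study_ids=[s.study_id for s in studies],
        drop_counts=drop_counts,
    )


def write_results(results, path, *, dataset: MergedDataset | None = None, binning=None) -> None:
    """Write per-SNP method results as TSV, one row per SNP.

    ``results`` is a flat list of MethodResult records (one per SNP per
    method); they are pivoted wide so each method contributes statistic,
    p-value and significance columns.  Rows are ordered by ascending modRP
    p-value (falling back to the first method present), ties broken by
    snp_id.  Floats are printed with 12 significant digits so a read-back
    reproduces the values.
    """
    if not results:
        raise ValueError("results must be non-empty")
    rows = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "significant": [int(r.significant) for r in results],
        }
    )
    wide = rows.pivot(index="snp_id", columns="method")
    methods = [m for m in ("fisher", "mod_fisher", "rp", "modrp") if m in set(rows["method"])]
    out = pd.DataFrame(index=wide.index)
    if dataset is not None:
        meta = pd.DataFrame(
            {
                "chromosome": dataset.chromosomes,
                "position": dataset.positions,
                "maf": dataset.mafs,
            },
            index=pd.Index(dataset.snp_ids, name="snp_id"),
        )
        if binning is not None:
            meta["maf_bin"] = binning.bin_of
        out = out.join(meta, how="left")
    for m in methods:
        out[f"{m}_statistic"] = wide[("statistic", m)]
        out[f"{m}_p"] = wide[("p", m)]
        out[f"{m}_significant"] = wide[("significant", m)].astype(int)
    sort_method = "modrp" if "modrp" in methods else methods[0]
    out = out.sort_values([f"{sort_method}_p", "snp_id"], kind="stable")
    out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
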