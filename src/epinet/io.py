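"""Genotype and annotation I/O.

Containers for case-control genotype data and gene models, plus readers and
writers for the standard on-disk formats the pipeline touches:

* PLINK bed/bim/fam triplets (variant-major, 2-bit packed hard calls);
* BED6+ gene/promoter annotation (0-based half-open intervals, gene id in the
  name column);
* tab-separated result tables;
* a plain-text dosage matrix fallback for tiny fixtures.

Coordinate conventions are explicit throughout: variant positions are 1-based
(bim convention), annotation intervals are 0-based half-open (BED convention),
and a variant at 1-based position ``p`` falls inside interval ``[s, e)`` iff
``s <= p - 1 < e``.

Dosages count copies of the *minor* allele (the lower-frequency allele over
non-missing calls in the loaded data); the orientation chosen per variant is
recorded so that results are reproducible. Missing genotypes are coded ``-1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

PHENO_CONTROL = 0
PHENO_CASE = 1
PHENO_MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_VARIANT_MAJOR = 0x01

# PLINK 2-bit genotype codes (counting A1 alleles):
#   00 -> hom A1 (dosage 2), 01 -> missing, 10 -> het, 11 -> hom A2 (dosage 0)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class Variant:
    variant_id: str
    chrom: str
    pos: int  # 1-based
    a1: str
    a2: str
    minor_is_a1: bool = True


@dataclass
class Sample:
    sample_id: str
    phenotype: int  # PHENO_CONTROL / PHENO_CASE / PHENO_MISSING


@dataclass
class GenotypeDataset:
    """Case-control genotypes: samples x variants minor-allele dosage matrix.

    ``dosages`` has shape ``(n_samples, n_variants)`` with entries in
    ``{0, 1, 2, MISSING}``.
    """

    samples: list[Sample]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def phenotypes(self) -> np.ndarray:
        return np.array([s.phenotype for s in self.samples], dtype=np.int8)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def variant_index(self) -> dict[str, int]:
        return {v.variant_id: i for i, v in enumerate(self.variants)}

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Row/column subset preserving order of the given indices."""
        s_idx = (np.arange(self.n_samples) if sample_idx is None
                 else np.asarray(sample_idx, dtype=np.intp))
        v_idx = (np.arange(self.n_variants) if variant_idx is None
                 else np.asarray(variant_idx, dtype=np.intp))
        return GenotypeDataset(
            samples=[self.samples[i] for i in s_idx],
            variants=[self.variants[j] for j in v_idx],
            dosages=self.dosages[np.ix_(s_idx, v_idx)].copy(),
        )


@dataclass
class GeneModel:
    """A gene's genomic intervals (body plus promoter) for SNP assignment.

    Intervals are 0-based half-open ``(start, end)`` pairs, each tagged with
    its source (``"body"`` or ``"promoter"``).
    """

    gene_id: str
    chrom: str
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e, tag in self.intervals:
            if not s < e:
                raise ValueError(f"gene {self.gene_id}: empty interval [{s}, {e})")
            if tag not in ("body", "promoter"):
                raise ValueError(f"gene {self.gene_id}: unknown interval tag {tag!r}")

    def contains(self, pos_1based: int, sources: tuple[str, ...] = ("body", "promoter")) -> bool:
        p0 = pos_1based - 1
        return any(s <= p0 < e for s, e, tag in self.intervals if tag in sources)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def _orient_to_minor(dosages: np.ndarray, variants: list[Variant]) -> None:
    """Flip per-variant dosage orientation so dosages count the minor allele.

    Minor allele = lower-frequency allele over non-missing calls; an exact
    50/50 tie keeps A1 as minor.
    """
    for j, v in enumerate(variants):
        col = dosages[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            v.minor_is_a1 = True
            continue
        freq_a1 = float(obs.sum()) / (2.0 * obs.size)
        if freq_a1 > 0.5:
            col[col != MISSING] = 2 - col[col != MISSING]
            v.minor_is_a1 = False
        else:
            v.minor_is_a1 = True


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK bed/bim/fam triplet into a :class:`GenotypeDataset`.

    Only variant-major bed files are supported. Dosages are re-oriented to
    minor-allele counts computed from the loaded data. fam phenotype codes:
    1 = control, 2 = case, 0 or -9 = missing.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str, "fid": str},
    )
    pheno_map = {1: PHENO_CONTROL, 2: PHENO_CASE, 0: PHENO_MISSING, -9: PHENO_MISSING}
    samples = []
    for _, row in fam.iterrows():
        code = int(row["pheno"])
        if code not in pheno_map:
            raise FormatError(f"{fam_path}: unknown phenotype code {code}")
        samples.append(Sample(sample_id=str(row["iid"]), phenotype=pheno_map[code]))

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "vid": str, "a1": str, "a2": str},
    )
    variants = [
        Variant(variant_id=row.vid, chrom=row.chrom, pos=int(row.pos), a1=row.a1, a2=row.a2)
        for row in bim.itertuples()
    ]

    n_samples, n_variants = len(samples), len(variants)
    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes")
    if raw[2] != _BED_VARIANT_MAJOR:
        raise FormatError(f"{bed_path}: sample-major bed files are not supported")
    bytes_per_variant = (n_samples + 3) // 4
    expected = 3 + bytes_per_variant * n_variants
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: expected {expected} bytes for {n_samples} samples x "
            f"{n_variants} variants, found {len(raw)} (truncated or fam/bim mismatch)"
        )

    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if n_variants == 0:
        dosages = np.zeros((n_samples, 0), dtype=np.int8)
    else:
        body = body.reshape(n_variants, bytes_per_variant)
        # unpack 2-bit codes, low bits first within each byte (PLINK order)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = (body[:, :, None] >> shifts) & 0b11  # (variant, byte, 4)
        codes = codes.reshape(n_variants, bytes_per_variant * 4)[:, :n_samples]
        dosages = _CODE_TO_DOSAGE[codes].T.copy()  # samples x variants

    _orient_to_minor(dosages, variants)
    return GenotypeDataset(samples=samples, variants=variants, dosages=dosages)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write bed/bim/fam. A1 is the recorded minor allele of each variant."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in dataset.samples:
            code = {PHENO_CONTROL: 1, PHENO_CASE: 2, PHENO_MISSING: -9}[s.phenotype]
            fh.write(f"{s.sample_id} {s.sample_id} 0 0 0 {code}\n")

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in dataset.variants:
            a1, a2 = (v.a1, v.a2) if v.minor_is_a1 else (v.a2, v.a1)
            fh.write(f"{v.chrom}\t{v.variant_id}\t0\t{v.pos}\t{a1}\t{a2}\n")

    n_samples, n_variants = dataset.n_samples, dataset.n_variants
    bytes_per_variant = (n_samples + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        code_lut[dos % 4] = code  # MISSING=-1 -> index 3
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_VARIANT_MAJOR]))
        if n_variants:
            codes = code_lut[dataset.dosages.T % 4].astype(np.uint8)  # variant x sample
            padded = np.zeros((n_variants, bytes_per_variant * 4), dtype=np.uint8)
            padded[:, :n_samples] = codes
            padded = padded.reshape(n_variants, bytes_per_variant, 4)
            shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
            packed = (padded << shifts).sum(axis=2).astype(np.uint8)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Annotation BED


def read_annotation_bed(path: str | Path) -> list[GeneModel]:
    """Read BED6+ annotation into gene models.

    Column 4 (name) carries the gene id, optionally suffixed ``|body`` or
    ``|promoter`` to tag the interval source (untagged rows default to body).
    Rows sharing a gene id merge into one model. Intervals stay 0-based
    half-open.
    """
    path = Path(path)
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: empty interval [{start}, {end})")
            gene_id, _, tag = name.partition("|")
            tag = tag or "body"
            model = models.get(gene_id)
            if model is None:
                models[gene_id] = GeneModel(gene_id=gene_id, chrom=chrom, intervals=[(start, end, tag)])
            else:
                if model.chrom != chrom:
                    raise FormatError(f"{path}:{lineno}: gene {gene_id} spans chromosomes")
                model.intervals.append((start, end, tag))
    return list(models.values())


def write_annotation_bed(gene_models: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gm in gene_models:
            for start, end, tag in gm.intervals:
                fh.write(f"{gm.chrom}\t{start}\t{end}\t{gm.gene_id}|{tag}\t0\t+\n")


# ---------------------------------------------------------------------------
# Result tables

_PVALUE_FIELDS = {"p", "p_screen", "p_wald", "best_p"}
_OR_FIELDS = {"or_value"}


def _format_value(name: str, value) -> str:
    if value is None:
        return "NA"
    # 17 significant digits: lossless float round-trips; p-values stay in
    # scientific notation and odds ratios keep >= 6 significant digits
    if name in _PVALUE_FIELDS:
        return f"{value:.16e}"
    if name in _OR_FIELDS:
        return f"{value:.17g}"
    if isinstance(value, float):
        return f"{value:.17g}" if np.isfinite(value) else "NA"
    return str(value)


def write_results_tsv(records: Sequence, path: str | Path, record_type=None) -> None:
    """Write dataclass records as TSV: fixed header from the dataclass fields,
    p-values in scientific notation, odds ratios with 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if record_type is None:
        if not records:
            raise ValueError("record_type is required to write an empty table")
        record_type = type(records[0])
    names = [f.name for f in dataclasses.fields(record_type)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for rec in records:
            fh.write("\t".join(_format_value(n, getattr(rec, n)) for n in names) + "\n")


def read_results_tsv(path: str | Path, record_type) -> list:
    """Read back a TSV written by :func:`write_results_tsv`."""
    path = Path(path)
    fields = {f.name: f for f in dataclasses.fields(record_type)}
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        unknown = set(header) - set(fields)
        if unknown:
            raise FormatError(f"{path}: unknown columns {sorted(unknown)}")
        for line in fh:
            values = line.rstrip("\n").split("\t")
            kwargs = {}
            for name, raw in zip(header, values):
                if raw == "NA":
                    kwargs[name] = None
                    continue
                ftype = fields[name].type
                if ftype in ("int", int):
                    kwargs[name] = int(raw)
                elif ftype in ("float", float, "float | None"):
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = raw
            out.append(record_type(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Plain-text fallback


def read_dosage_tsv(path: str | Path) -> GenotypeDataset:
    """Read the plain-text fallback format: a sample x variant dosage table.

    First column ``sample_id``, second ``phenotype`` (``case``/``control``/
    ``missing``), remaining columns one per variant id; entries 0/1/2 or NA.
    Variant positions are taken as 1-based column order; chromosome ``1``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    pheno_codes = {"control": PHENO_CONTROL, "case": PHENO_CASE, "missing": PHENO_MISSING}
    samples = [
        Sample(sample_id=r.sample_id, phenotype=pheno_codes[r.phenotype])
        for r in df.itertuples()
    ]
    vids = [c for c in df.columns if c not in ("sample_id", "phenotype")]
    variants = [Variant(variant_id=v, chrom="1", pos=i + 1, a1="A", a2="B") for i, v in enumerate(vids)]
    dosages = df[vids].to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    return GenotypeDataset(samples=samples, variants=variants, dosages=dosages)
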