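"""Readers/writers for the formats the pipeline touches, plus hard filtering.

Coordinate conventions: VCF and GFF3 are 1-based inclusive on disk; all
internal interval arithmetic is 0-based half-open.  Conversion happens only
at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("haplopop")

MISSING = -1  # allele index marking an uncalled allele

#: annotation keys understood in the INFO column
SITE_ANNOTATIONS = ("QD", "FS", "MQ", "SOR", "DP", "MQRankSum", "ReadPosRankSum")


class VcfParseError(ValueError):
    """Raised for a malformed VCF header or record."""


class FilterConfigError(ValueError):
    """Raised when a filter rule references an unknown annotation in strict mode."""


@dataclass
class VariantTable:
    """Multi-sample variant records with genotypes and site annotations.

    Attributes
    ----------
    chrom, pos : arrays of chromosome name and 1-based position per record.
    ref, alt : reference allele and list of alternate alleles per record.
    annotations : mapping annotation name -> float array (NaN where absent).
    genotypes : int array of shape (n_sites, n_samples, 2); ``MISSING`` (-1)
        marks an uncalled allele.
    samples : ordered sample ids.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: list
    alt: list
    annotations: dict
    genotypes: np.ndarray
    samples: list

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        n = self.n_sites
        if not (len(self.ref) == len(self.alt) == len(self.pos) == n):
            raise ValueError("ragged variant table")

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in table") from None

    def take_sites(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            annotations={k: v[idx] for k, v in self.annotations.items()},
            genotypes=self.genotypes[idx],
            samples=list(self.samples),
        )

    def subset_samples(self, ids: Sequence[str]) -> "VariantTable":
        j = self.sample_index(ids)
        return VariantTable(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=list(self.ref),
            alt=list(self.alt),
            annotations={k: v.copy() for k, v in self.annotations.items()},
            genotypes=self.genotypes[:, j, :],
            samples=list(ids),
        )

    def called_fraction(self) -> np.ndarray:
        """Per-site fraction of samples with a fully called genotype."""
        called = np.all(self.genotypes != MISSING, axis=2)
        return called.mean(axis=1) if self.n_samples else np.zeros(self.n_sites)

    def is_biallelic_snp(self) -> np.ndarray:
        return np.array(
            [len(a) == 1 and len(r) == 1 and len(a[0]) == 1 for r, a in zip(self.ref, self.alt)],
            dtype=bool,
        )

    def dosage(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Alternate-allele dosage matrix (sites x samples), NaN where missing."""
        gt = self.genotypes if samples is None else self.genotypes[:, self.sample_index(samples), :]
        d = (gt > 0).sum(axis=2).astype(float)
        d[np.any(gt == MISSING, axis=2)] = np.nan
        return d


@dataclass
class SampleSheet:
    """Sample metadata: population label, cultivar group and geography."""

    table: pd.DataFrame  # index sample_id; columns population, cultivar_group, geography

    VALID_GROUPS = frozenset({"EEMC", "EMC", "LMC", "wild"})

    def __post_init__(self):
        for col in ("population", "cultivar_group"):
            if col not in self.table.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
            if (self.table[col].astype(str).str.len() == 0).any():
                raise ValueError(f"empty {col} label in sample sheet")
        bad = set(self.table["cultivar_group"]) - self.VALID_GROUPS
        if bad:
            raise ValueError(f"unknown cultivar groups: {sorted(bad)}")

    @classmethod
    def read(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
        if "geography" not in df.columns:
            df["geography"] = "NA"
        return cls(df)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")

    def population_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "population"])

    def samples_in(self, population: str) -> list:
        return list(self.table.index[self.table["population"] == population])

    def validate_against(self, vt: VariantTable) -> None:
        missing = set(vt.samples) - set(self.table.index)
        if missing:
            raise ValueError(f"samples absent from sheet: {sorted(missing)}")


@dataclass(frozen=True)
class Predicate:
    annotation: str
    comparator: str  # "<" or ">"
    threshold: float

    def fails(self, value: float) -> bool:
        if np.isnan(value):
            return False  # handled by caller according to strictness
        return value < self.threshold if self.comparator == "<" else value > self.threshold


@dataclass
class FilterRule:
    """A GATK-style hard filter: a site fails if ANY predicate is true."""

    name: str
    predicates: list

    @classmethod
    def parse(cls, expression: str, name: str = "custom") -> "FilterRule":
        """Parse a ``QD < 2.0 || FS > 60.0`` style expression."""
        preds = []
        for clause in expression.split("||"):
            parts = clause.split()
            if len(parts) != 3 or parts[1] not in ("<", ">"):
                raise ValueError(f"cannot parse filter clause {clause.strip()!r}")
            preds.append(Predicate(parts[0], parts[1], float(parts[2])))
        return cls(name=name, predicates=preds)


# Hard-filter presets; expressions exactly as used for the resequencing panel
# ("population") and for the phasing SNP set ("phasing").
PRESETS = {
    "population": FilterRule.parse(
        "DP < 300 || DP > 3000 || QD < 2.0 || FS > 60.0 || MQ < 40.0 "
        "|| MQRankSum < -12.5 || ReadPosRankSum < -8.0",
        name="population",
    ),
    "phasing": FilterRule.parse(
        "QD < 2.0 || MQ < 26.0 || FS > 100.0 || SOR > 5.0 "
        "|| MQRankSum < -7.5 || ReadPosRankSum < -8.0",
        name="phasing",
    ),
}


def read_vcf(path, biallelic_only: bool = False) -> VariantTable:
    """Read a VCF 4.x file into a :class:`VariantTable`.

    Multiallelic records are dropped (and counted in the log) when
    ``biallelic_only`` is set.  Missing genotypes are preserved as missing.
    """
    from cyvcf2 import VCF

    path = str(path)
    _sanity_check_header(path)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, gts = [], [], [], [], []
    ann = {k: [] for k in SITE_ANNOTATIONS}
    n_multi = 0
    for rec in vcf:
        if biallelic_only and len(rec.ALT) != 1:
            n_multi += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(list(rec.ALT))
        g = np.array(rec.genotypes, dtype=object) if samples else np.empty((0, 3))
        if samples:
            pair = np.array([[a if a is not None and a >= 0 else MISSING for a in row[:2]] for row in rec.genotypes], dtype=np.int16)
        else:
            pair = np.empty((0, 2), dtype=np.int16)
        gts.append(pair)
        for k in SITE_ANNOTATIONS:
            v = rec.INFO.get(k)
            ann[k].append(float(v) if v is not None else np.nan)
    vcf.close()
    if n_multi:
        logger.info("read_vcf: excluded %d multiallelic records", n_multi)
    n = len(chroms)
    table = VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64) if n else np.empty(0, dtype=np.int64),
        ref=refs,
        alt=alts,
        annotations={k: np.array(v, dtype=float) if n else np.empty(0) for k, v in ann.items()},
        genotypes=np.array(gts, dtype=np.int16) if n else np.empty((0, len(samples), 2), dtype=np.int16),
        samples=samples,
    )
    return table


def _sanity_check_header(path: str) -> None:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VcfParseError(f"{path}: line 1: missing ##fileformat=VCF header")


def write_vcf(vt: VariantTable, path) -> None:
    """Write the supported field subset (CHROM/POS/REF/ALT/INFO subset/GT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k in SITE_ANNOTATIONS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(map(str, vt.chrom))):
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + vt.samples
        fh.write("\t".join(cols) + "\n")
        for i in range(vt.n_sites):
            info = ";".join(
                f"{k}={_fmt(vt.annotations[k][i])}"
                for k in SITE_ANNOTATIONS
                if k in vt.annotations and not np.isnan(vt.annotations[k][i])
            ) or "."
            gts = [
                "/".join("." if a == MISSING else str(int(a)) for a in vt.genotypes[i, j])
                for j in range(vt.n_samples)
            ]
            row = [str(vt.chrom[i]), str(int(vt.pos[i])), ".", vt.ref[i], ",".join(vt.alt[i]), ".", ".", info, "GT"] + gts
            fh.write("\t".join(row) + "\n")


def _fmt(x: float) -> str:
    s = f"{x:.6g}"
    return s


def apply_hard_filter(vt: VariantTable, rule: FilterRule, strict: bool = False):
    """Remove sites failing ANY predicate of ``rule``.

    Returns ``(filtered_table, fail_counts)`` where ``fail_counts`` maps
    ``"<annotation><cmp><threshold>"`` to the number of sites that failed that
    predicate (a site may fail several, so counts can sum to more than the
    number removed).

    Sites missing a referenced annotation are retained with a warning in
    lenient mode (the default) and raise :class:`FilterConfigError` in strict
    mode.
    """
    keep = np.ones(vt.n_sites, dtype=bool)
    fail_counts = {}
    for pred in rule.predicates:
        key = f"{pred.annotation}{pred.comparator}{pred.threshold:g}"
        values = vt.annotations.get(pred.annotation)
        if values is None:
            values = np.full(vt.n_sites, np.nan)
        n_absent = int(np.isnan(values).sum())
        if n_absent and strict:
            raise FilterConfigError(
                f"annotation {pred.annotation!r} absent at {n_absent} sites (strict mode)"
            )
        if n_absent:
            logger.warning(
                "filter %s: annotation %s missing at %d sites; retained (lenient mode)",
                rule.name, pred.annotation, n_absent,
            )
        with np.errstate(invalid="ignore"):
            failed = values < pred.threshold if pred.comparator == "<" else values > pred.threshold
        failed = np.asarray(failed) & ~np.isnan(values)
        fail_counts[key] = int(failed.sum())
        keep &= ~failed
    out = vt.take_sites(keep)
    logger.info("filter %s: removed %d of %d sites", rule.name, vt.n_sites - out.n_sites, vt.n_sites)
    return out, fail_counts


def missingness_filter(vt: VariantTable, min_called_fraction: float) -> VariantTable:
    """Keep sites where the called-genotype fraction strictly exceeds the threshold."""
    if not 0 <= min_called_fraction <= 1:
        raise ValueError("min_called_fraction must be in [0, 1]")
    return vt.take_sites(vt.called_fraction() > min_called_fraction)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BED / TSV helpers

def read_fasta(path) -> dict:
    """Read a FASTA file into {name: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: Iterable, path) -> None:
    """Write gene models (see :class:`haplopop.variant_impact.GeneModel`) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g0, g1 = m.span()
            fh.write(
                f"{m.chrom}\t.\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\t.\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(f"{m.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={m.gene_id}.t1\n")
            for s, e in m.cds:
                fh.write(f"{m.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={m.gene_id}.t1\n")


def read_gff3(path) -> list:
    """Read gene models from the 9-column GFF3 subset written by this package."""
    from .variant_impact import GeneModel

    genes: dict = {}
    order = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line.strip()!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = f
            attrd = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            if ftype == "gene":
                gid = attrd["ID"]
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": [], "cds": []}
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                gid = attrd["Parent"].rsplit(".t1", 1)[0]
                genes[gid]["exons" if ftype == "exon" else "cds"].append(iv)
    out = []
    for gid in order:
        g = genes[gid]
        exons = sorted(g["exons"])
        cds = sorted(g["cds"])
        span = (exons[0][0], exons[-1][1]) if exons else (0, 0)
        tss = span[0] if g["strand"] == "+" else span[1] - 1
        out.append(GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"], exons=exons, cds=cds, tss=tss))
    return out


def read_depth_bed(path) -> pd.DataFrame:
    """Read a per-base depth track: chrom, start (0-based), end, depth."""
    return pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "depth"], header=None)


def write_depth_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped, level-tagged logging to stderr."""
    h = logging.StreamHandler()
    h.setFormatter(logging.Formatter("%(asctime)s [%(levelname)s] %(name)s: %(message)s"))
    logger.handlers[:] = [h]
    logger.setLevel(level)


def load_config(path) -> dict:
    """Load the structured (YAML key/value + nested sections) config file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg
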