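"""Readers and writers for every on-disk representation the pipeline touches.

Coordinate conventions are fixed per format and never guessed:

* pileup TSV and VCF are 1-based, fully closed;
* BED and bedGraph are 0-based, half-open;
* :class:`GeneModel` intervals are 0-based, half-open (the internal
  convention for all interval arithmetic).

Pileup tables are strand-resolved: every row names the transcribed strand
the counts belong to, as produced by a stranded RNA-seq protocol.
Unstranded input (a strand value other than ``+``/``-``) is rejected.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pyfaidx

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

PILEUP_COLUMNS = ["contig", "pos", "strand", "ref", "A", "C", "G", "T"]
BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class PileupTable:
    """Per-sample, strand-resolved base counts at covered reference positions.

    ``df`` holds one row per (contig, pos, strand) with 1-based ``pos``, the
    genomic reference base ``ref`` and non-negative counts for A/C/G/T as
    observed on the genomic forward strand.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PILEUP_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"pileup table missing columns: {missing}")
        bad_strand = set(self.df["strand"].unique()) - {"+", "-"}
        if bad_strand:
            raise ValidationError(
                f"unstranded or malformed strand values: {sorted(bad_strand)}"
            )
        counts = self.df[list(BASES)].to_numpy()
        if (counts < 0).any():
            raise ValidationError("negative base count in pileup table")
        if self.df.duplicated(subset=["contig", "pos", "strand"]).any():
            raise ValidationError("duplicate (contig, pos, strand) in pileup table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def totals(self) -> np.ndarray:
        return self.df[list(BASES)].to_numpy().sum(axis=1)


@dataclass(frozen=True)
class GeneModel:
    """One transcript's structure: ordered exons plus optional CDS intervals.

    All intervals are 0-based half-open on the genomic forward strand.
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if e0 > s1:
                raise ValidationError(f"overlapping exons in {self.gene_id}")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in exons):
                raise ValidationError(f"CDS outside exons in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)


@dataclass(frozen=True)
class ExclusionSet:
    """Deduplicated point positions (1-based) to remove from editing calls."""

    points: frozenset = field(default_factory=frozenset)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.points

    def __len__(self) -> int:
        return len(self.points)

    def __or__(self, other: "ExclusionSet") -> "ExclusionSet":
        return ExclusionSet(self.points | other.points)

    @classmethod
    def from_keys(cls, keys: Iterable[tuple[str, int]]) -> "ExclusionSet":
        return cls(frozenset((str(c), int(p)) for c, p in keys))


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------


def read_pileup_table(
    path: str | Path,
    min_coverage: int = 5,
    sample_id: str | None = None,
) -> PileupTable:
    """Read a tab-separated pileup table and drop low-coverage rows.

    The file must carry the documented header
    ``contig pos strand ref A C G T``. Rows whose total count is below
    ``min_coverage`` are removed (a site needs at least that many covering
    reads to be evaluated at all). Rows come back sorted by (contig, pos).
    """
    if min_coverage < 0:
        raise ValidationError("min_coverage must be >= 0")
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "contig": str,
                "pos": np.int64,
                "strand": str,
                "ref": str,
                **{b: np.int64 for b in BASES},
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed pileup table: {exc}") from exc
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: pileup header missing columns {missing}")
    df = df[PILEUP_COLUMNS]
    counts = df[list(BASES)].to_numpy()
    if (counts < 0).any():
        row = int(np.argwhere((counts < 0).any(axis=1))[0][0])
        raise ValidationError(f"{path}: negative count at data line {row + 1}")
    bad_ref = ~df["ref"].isin(BASES)
    if bad_ref.any():
        row = int(np.argwhere(bad_ref.to_numpy())[0][0])
        raise FormatError(f"{path}: invalid ref base at data line {row + 1}")
    keep = counts.sum(axis=1) >= min_coverage
    df = df[keep].sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
    return PileupTable(sample_id=sample_id or path.stem, df=df)


def write_pileup_table(table: PileupTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def pool_pileups(tables: list[PileupTable], sample_id: str = "pooled") -> PileupTable:
    """Sum base counts across replicate tables at matching (contig, pos, strand).

    The reference base must agree wherever rows coincide.
    """
    if not tables:
        raise ValidationError("no pileup tables to pool")
    if len(tables) == 1:
        return PileupTable(sample_id, tables[0].df.copy())
    cat = pd.concat([t.df for t in tables], ignore_index=True)
    grouped = cat.groupby(["contig", "pos", "strand"], sort=True)
    if (grouped["ref"].nunique() > 1).any():
        raise ValidationError("reference base disagrees across pooled replicates")
    pooled = grouped.agg(
        ref=("ref", "first"), **{b: (b, "sum") for b in BASES}
    ).reset_index()
    return PileupTable(sample_id, pooled[PILEUP_COLUMNS])


# ---------------------------------------------------------------------------
# exclusion lists (VCF / BED)
# ---------------------------------------------------------------------------


def read_exclusions(path: str | Path) -> ExclusionSet:
    """Load known-variant positions from a VCF or BED file.

    The format is auto-detected by extension; everything is normalized to
    1-based point positions and deduplicated. BED intervals contribute every
    position they cover.
    """
    path = Path(path)
    suffixes = [s.lower() for s in path.suffixes]
    if ".vcf" in suffixes:
        return _read_vcf_points(path)
    if ".bed" in suffixes:
        return _read_bed_points(path)
    raise FormatError(f"{path}: unknown exclusion-list extension (want .vcf or .bed)")


def _read_vcf_points(path: Path) -> ExclusionSet:
    from cyvcf2 import VCF

    points = set()
    for rec in VCF(str(path)):
        points.add((rec.CHROM, rec.POS))
    return ExclusionSet(frozenset(points))


def _read_bed_points(path: Path) -> ExclusionSet:
    points = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED fields")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            # 0-based half-open interval -> 1-based points
            points.update((contig, p) for p in range(start + 1, end + 1))
    return ExclusionSet(frozenset(points))


# ---------------------------------------------------------------------------
# site / comparison track output
# ---------------------------------------------------------------------------


def write_sites_bed(sites: Iterable, path: str | Path) -> None:
    """Write editing sites as BED6 (name = edit type, score = 1000 x rate)."""
    rows = []
    for s in sites:
        rows.append(
            (
                s.contig,
                s.position - 1,
                s.position,
                s.edit_type,
                int(round(1000 * s.rate)),
                s.gene_strand,
            )
        )
    try:
        rows.sort(key=lambda r: (r[0], r[1]))
    except TypeError as exc:
        raise ValidationError(f"unsortable contig names: {exc}") from exc
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_delta_bedgraph(comparisons: Iterable, path: str | Path) -> None:
    """Write per-site delta editing rate (RBP minus control) as bedGraph."""
    rows = sorted(
        (c.contig, c.position - 1, c.position, c.rate_rbp - c.rate_ctrl)
        for c in comparisons
    )
    with open(path, "w") as fh:
        for contig, start, end, delta in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{delta:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA / GTF
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a reference FASTA into a contig -> upper-case sequence mapping."""
    fa = pyfaidx.Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Parse a GTF into per-transcript :class:`GeneModel` records."""
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            tx = feat.attributes.get("transcript_id", [""])[0]
            gene = feat.attributes.get("gene_id", [tx])[0]
            rec = by_tx.setdefault(
                tx,
                {
                    "gene_id": gene,
                    "contig": feat.seqid,
                    "strand": feat.strand,
                    "exons": [],
                    "cds": [],
                },
            )
            # GTF is 1-based closed; convert to 0-based half-open
            interval = (feat.start - 1, feat.end)
            rec["exons" if ftype == "exon" else "cds"].append(interval)
    models = []
    for tx, rec in by_tx.items():
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                contig=rec["contig"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                cds=tuple(rec["cds"]),
                transcript_id=tx,
            )
        )
    models.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return models


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Serialize gene models as GTF (exon and CDS features)."""
    with open(path, "w") as fh:
        for g in models:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id or g.gene_id}";'
            for ftype, intervals in (("exon", g.exons), ("CDS", g.cds)):
                for s, e in intervals:
                    fh.write(
                        f"{g.contig}\trbpedit\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


SITES_COLUMNS = [
    "contig",
    "position",
    "gene_strand",
    "edit_type",
    "ref_count",
    "edit_count",
    "other_count",
    "rate",
    "gene_id",
]


def write_sites_tsv(sites: Iterable, path: str | Path) -> None:
    """Write editing sites as a TSV with the documented column set."""
    rows = [
        {
            "contig": s.contig,
            "position": s.position,
            "gene_strand": s.gene_strand,
            "edit_type": s.edit_type,
            "ref_count": s.ref_count,
            "edit_count": s.edit_count,
            "other_count": s.other_count,
            "rate": s.rate,
            "gene_id": s.gene_id,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITES_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path):
    """Read a sites TSV back into :class:`~rbpedit.editing_detection.EditingSite`s."""
    from .editing_detection import EditingSite

    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene_id": str})
    df["gene_id"] = df["gene_id"].fillna("")
    return [
        EditingSite(
            contig=r.contig,
            position=int(r.position),
            gene_strand=r.gene_strand,
            edit_type=r.edit_type,
            ref_count=int(r.ref_count),
            edit_count=int(r.edit_count),
            other_count=int(r.other_count),
            gene_id=r.gene_id,
        )
        for r in df.itertuples(index=False)
    ]


def write_vcf_points(
    points: Iterable[tuple[str, int, str, str]], path: str | Path
) -> None:
    """Write (contig, 1-based pos, ref, alt) records as a minimal VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt in sorted(points):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
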