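"""Readers/writers for genomic inputs, SNP-swapped genomes, CpG discovery, cell QC.

Coordinate conventions: per-site tables are 1-based (allc convention);
all intervals (genes, chromatin states, segments) are 0-based half-open
(BED convention).

A site table is a :class:`pandas.DataFrame` with columns
``chrom, pos, strand, context`` followed by ``<strain>.mc`` / ``<strain>.cov``
pairs, one pair per strain, mirroring the combined multi-strain data frame
used throughout the analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_CONTEXTS = frozenset({"CG", "CH"})
VALID_STRANDS = frozenset({"+", "-"})
NUCLEOTIDES = frozenset("ACGT")

#: the fixed 15 chromatin-state group vocabulary ("artifacts" excluded)
CHROMATIN_STATES = (
    "Active enhancers",
    "Bivalent promoters",
    "DNAase open chromatin",
    "Heterochromatin",
    "Polycomb repressed",
    "Polycomb repressed and open chromatin",
    "Promoter flank",
    "Quiescent",
    "Transcribed enhancers",
    "Transcription",
    "Transcription and exons",
    "Transcription start sites",
    "Weak enhancers",
    "Weak transcription",
    "Zinc finger genes",
)


class SiteTableError(ValueError):
    """Raised when a site table violates its invariants."""


class VariantError(ValueError):
    """Raised for malformed or inconsistent variant records."""


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

_MC_RE = re.compile(r"^(?P<strain>.+)\.mc$")


def site_table_strains(table: pd.DataFrame) -> list[str]:
    """Strain names encoded in the ``<strain>.mc`` / ``<strain>.cov`` columns."""
    strains = []
    for col in table.columns:
        m = _MC_RE.match(col)
        if m:
            strain = m.group("strain")
            if f"{strain}.cov" not in table.columns:
                raise SiteTableError(f"column {col!r} has no matching {strain}.cov")
            strains.append(strain)
    return strains


def validate_site_table(table: pd.DataFrame) -> None:
    """Check site-table invariants; raise :class:`SiteTableError` naming the first bad row."""
    required = ["chrom", "pos", "strand", "context"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SiteTableError(f"missing required columns: {missing}")
    strains = site_table_strains(table)
    if not strains:
        raise SiteTableError("no <strain>.mc/<strain>.cov column pairs found")
    if len(table) == 0:
        return
    if (table["pos"] < 1).any():
        row = int(table.index[table["pos"] < 1][0])
        raise SiteTableError(f"row {row}: pos < 1")
    bad_ctx = ~table["context"].isin(VALID_CONTEXTS)
    if bad_ctx.any():
        row = int(table.index[bad_ctx][0])
        raise SiteTableError(
            f"row {row}: unknown context {table.loc[row, 'context']!r}"
        )
    bad_strand = ~table["strand"].isin(VALID_STRANDS)
    if bad_strand.any():
        row = int(table.index[bad_strand][0])
        raise SiteTableError(f"row {row}: bad strand {table.loc[row, 'strand']!r}")
    for s in strains:
        mc, cov = table[f"{s}.mc"], table[f"{s}.cov"]
        if (mc < 0).any() or (cov < 0).any():
            row = int(table.index[(mc < 0) | (cov < 0)][0])
            raise SiteTableError(f"row {row}: negative count for strain {s}")
        over = mc > cov
        if over.any():
            row = int(table.index[over][0])
            raise SiteTableError(
                f"row {row}: {s}.mc={int(mc[row])} exceeds {s}.cov={int(cov[row])}"
            )


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV site table and validate it.

    The dialect is a header line naming ``chrom pos strand context`` and the
    per-strain ``<strain>.mc``/``<strain>.cov`` columns, one row per cytosine.
    Row order is preserved. A header-only file yields an empty, valid table.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if len(table):
        table["pos"] = table["pos"].astype(np.int64)
    try:
        validate_site_table(table)
    except SiteTableError as exc:
        raise SiteTableError(f"{path}: {exc} (line = row + 2 with header)") from exc
    return table


def write_site_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a site table in the canonical TSV dialect (round-trip stable)."""
    validate_site_table(table)
    table.to_csv(path, sep="\t", index=False)


def collapse_symmetric_cpgs(table: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of a symmetric CpG into one forward-strand record.

    A reverse-strand CG record at position ``p`` is pooled (mc and cov summed
    per strain) with the forward-strand record at ``p - 1`` when present, or
    re-keyed to ``p - 1`` otherwise.  CH records pass through unchanged.
    This is an explicit opt-in utility; no reader ever collapses implicitly.
    """
    validate_site_table(table)
    strains = site_table_strains(table)
    cg = table[table["context"] == "CG"].copy()
    ch = table[table["context"] != "CG"]
    rev = cg["strand"] == "-"
    cg.loc[rev, "pos"] = cg.loc[rev, "pos"] - 1
    cg["strand"] = "+"
    count_cols = [f"{s}.{k}" for s in strains for k in ("mc", "cov")]
    merged = (
        cg.groupby(["chrom", "pos"], as_index=False, sort=False)
        .agg({"strand": "first", "context": "first", **{c: "sum" for c in count_cols}})
    )
    out = pd.concat([merged, ch], ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def variant_table_strains(variants: pd.DataFrame) -> list[str]:
    return [c for c in variants.columns if c not in ("chrom", "pos", "ref")]


def validate_variants(variants: pd.DataFrame) -> None:
    required = ["chrom", "pos", "ref"]
    if [c for c in required if c not in variants.columns]:
        raise VariantError("variant table needs chrom, pos, ref columns")
    strains = variant_table_strains(variants)
    if not strains:
        raise VariantError("variant table has no strain allele columns")
    if len(variants) == 0:
        return
    allele_cols = ["ref"] + strains
    for c in allele_cols:
        bad = ~variants[c].isin(NUCLEOTIDES)
        if bad.any():
            row = int(variants.index[bad][0])
            raise VariantError(
                f"row {row}: non-SNV allele {variants.loc[row, c]!r} in column {c}"
            )


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    """Read the 3+N-column TSV variant dialect: chrom, pos (1-based), ref, one
    allele column per strain."""
    variants = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if len(variants):
        variants["pos"] = variants["pos"].astype(np.int64)
    validate_variants(variants)
    return variants


def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> None:
    validate_variants(variants)
    variants.to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Read SNVs from a VCF (v4.x); non-SNV records are skipped with a logged count.

    Each sample becomes a strain column; the first allele of the genotype is
    taken (inbred strains are homozygous). Missing genotypes fall back to ref.
    """
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alleles = [rec.ref] + [a for a in (rec.alts or ())]
            if len(rec.ref) != 1 or any(a is None or len(a) != 1 for a in alleles):
                skipped += 1
                continue
            row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref}
            for s in samples:
                gt = rec.samples[s].get("GT")
                idx = gt[0] if gt and gt[0] is not None else 0
                row[s] = alleles[idx]
            rows.append(row)
    if skipped:
        log.info("read_variants_vcf: skipped %d non-SNV records", skipped)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref"] + samples)
    validate_variants(variants)
    return variants


def read_variants(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` to the VCF reader, else TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_variants_vcf(path)
    return read_variants_tsv(path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA into a dict of upper-cased sequences."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SNP swapping & CpG discovery
# ---------------------------------------------------------------------------


def swap_snps(
    reference_sequence: str, variants: pd.DataFrame, strain: str, chrom: str | None = None
) -> str:
    """Substitute a strain's SNP alleles into the reference sequence.

    ``variants`` uses 1-based positions. Every ``ref`` allele must match the
    reference base at its position (guards coordinate off-by-one errors).
    The returned sequence differs from the reference exactly where the strain
    allele differs from the reference allele.
    """
    if strain not in variants.columns:
        raise VariantError(f"no allele column for strain {strain!r}")
    sub = variants if chrom is None else variants[variants["chrom"] == chrom]
    if len(sub) == 0:
        return reference_sequence
    pos = sub["pos"].to_numpy()
    if (pos < 1).any() or (pos > len(reference_sequence)).any():
        raise VariantError("variant position outside the sequence")
    seq = np.frombuffer(reference_sequence.encode(), dtype="S1").copy()
    refs = sub["ref"].to_numpy().astype("S1")
    found = seq[pos - 1]
    bad = found != refs
    if bad.any():
        i = int(np.argmax(bad))
        raise VariantError(
            f"ref allele mismatch at pos {int(pos[i])}: table says "
            f"{refs[i].decode()!r}, sequence has {found[i].decode()!r}"
        )
    seq[pos - 1] = sub[strain].to_numpy().astype("S1")
    return seq.tobytes().decode()


def _cpg_positions(sequence: str) -> np.ndarray:
    """1-based positions of the C of each forward-strand CG dinucleotide."""
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    if len(arr) < 2:
        return np.empty(0, dtype=np.int64)
    hits = (arr[:-1] == b"C") & (arr[1:] == b"G")
    return np.flatnonzero(hits).astype(np.int64) + 1


def _context5(sequence: str, pos: int) -> str:
    """5-bp context centred on a 1-based position, N-padded at chromosome ends."""
    left = pos - 3
    out = []
    for i in range(left, left + 5):
        out.append(sequence[i] if 0 <= i < len(sequence) else "N")
    return "".join(out)


def find_cpg_sites(
    genome_sequence: Mapping[str, str] | str,
    variants_per_strain: pd.DataFrame | None = None,
    strains: Sequence[str] | None = None,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Locate forward-strand CpG sites per strain, with 5-bp reference contexts.

    Scans the reference and each strain's SNP-swapped sequence for CG
    dinucleotides; each record carries the 1-based position of the C, the 5-bp
    context of the *reference* genome (N-padded at ends, never dropped), and
    flags for strain-specific gains/losses relative to the reference.

    Returns a long DataFrame: chrom, pos, context5, strain, in_reference,
    in_strain, gained, lost.  The pseudo-strain ``"reference"`` is always
    present.
    """
    if isinstance(genome_sequence, str):
        genome_sequence = {chrom: genome_sequence}
    if variants_per_strain is not None and strains is None:
        strains = variant_table_strains(variants_per_strain)
    strains = list(strains or [])

    frames = []
    for chrom_name, refseq in genome_sequence.items():
        per_strain_pos: dict[str, set[int]] = {
            "reference": set(_cpg_positions(refseq).tolist())
        }
        for s in strains:
            seq = (
                swap_snps(refseq, variants_per_strain, s, chrom=chrom_name)
                if variants_per_strain is not None
                else refseq
            )
            per_strain_pos[s] = set(_cpg_positions(seq).tolist())
        all_pos = sorted(set().union(*per_strain_pos.values()))
        for name, posset in per_strain_pos.items():
            if not all_pos:
                continue
            in_ref = np.array([p in per_strain_pos["reference"] for p in all_pos])
            in_strain = np.array([p in posset for p in all_pos])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom_name,
                        "pos": np.asarray(all_pos, dtype=np.int64),
                        "context5": [_context5(refseq, p) for p in all_pos],
                        "strain": name,
                        "in_reference": in_ref,
                        "in_strain": in_strain,
                        "gained": in_strain & ~in_ref,
                        "lost": in_ref & ~in_strain,
                    }
                )
            )
    if not frames:
        cols = [
            "chrom", "pos", "context5", "strain",
            "in_reference", "in_strain", "gained", "lost",
        ]
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    return out[out["in_strain"] | out["in_reference"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cell QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellQCRecord:
    """Per-cell QC metrics from single-nucleus bisulfite sequencing.

    mccc is the mCCC level (a bisulfite non-conversion proxy); mcg/mch are
    global CpG / non-CpG methylation fractions; coverage_pct is the percent of
    the genome covered. Any metric may be None (incomplete record).
    """

    cell_id: str
    mccc: float | None
    mcg: float | None
    mch: float | None
    mapped_reads: float | None
    mapping_rate: float | None
    coverage_pct: float | None


@dataclass(frozen=True)
class CellQCThresholds:
    """All six filters are strict inequalities."""

    max_mccc: float = 0.03
    min_mcg: float = 0.5
    max_mch: float = 0.2
    min_mapped_reads: float = 100_000
    min_mapping_rate: float = 0.5
    min_coverage_pct: float = 2.0


def cell_qc_filter(
    records: Iterable[CellQCRecord],
    thresholds: CellQCThresholds = CellQCThresholds(),
) -> tuple[list[CellQCRecord], list[CellQCRecord], list[CellQCRecord]]:
    """Partition cells into (passed, failed, incomplete).

    A cell passes when mCCC < 0.03, mCG > 0.5, mCH < 0.2, mapped reads >
    100,000, mapping rate > 0.5 and percent genome covered > 2 (defaults; all
    configurable, all strict). Records with any missing metric are returned
    separately as incomplete, not counted as QC failures.
    """
    passed, failed, incomplete = [], [], []
    for rec in records:
        metrics = [getattr(rec, f.name) for f in fields(rec) if f.name != "cell_id"]
        if any(m is None for m in metrics):
            incomplete.append(rec)
            continue
        ok = (
            rec.mccc < thresholds.max_mccc
            and rec.mcg > thresholds.min_mcg
            and rec.mch < thresholds.max_mch
            and rec.mapped_reads > thresholds.min_mapped_reads
            and rec.mapping_rate > thresholds.min_mapping_rate
            and rec.coverage_pct > thresholds.min_coverage_pct
        )
        (passed if ok else failed).append(rec)
    return passed, failed, incomplete


# ---------------------------------------------------------------------------
# gene models & chromatin states
# ---------------------------------------------------------------------------

REFGENE_COLUMNS = [
    "bin", "name", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
    "score", "name2", "cdsStartStat", "cdsEndStat", "exonFrames",
]


def read_genes_refgene(path: str | Path) -> pd.DataFrame:
    """Read a refGene-flat table into gene_id, chrom, strand, txStart, txEnd
    (0-based half-open)."""
    raw = pd.read_csv(path, sep="\t", header=None, names=REFGENE_COLUMNS, dtype={"chrom": str})
    genes = raw[["name", "chrom", "strand", "txStart", "txEnd"]].rename(
        columns={"name": "gene_id"}
    )
    return _validate_genes(genes)


def read_genes_gtf(path: str | Path) -> pd.DataFrame:
    """Extract transcript spans from a GTF (gene or transcript features)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    rows = []
    featuretypes = set(db.featuretypes())
    use = "gene" if "gene" in featuretypes else "transcript"
    for feat in db.features_of_type(use):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "txStart": feat.start - 1,  # gffutils is 1-based inclusive
                "txEnd": feat.end,
            }
        )
    return _validate_genes(pd.DataFrame(rows))


def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    if len(genes) and (genes["txStart"] >= genes["txEnd"]).any():
        bad = genes[genes["txStart"] >= genes["txEnd"]].iloc[0]
        raise ValueError(f"gene {bad['gene_id']}: txStart >= txEnd")
    return genes.reset_index(drop=True)


def read_genes(path: str | Path) -> pd.DataFrame:
    name = str(path)
    if name.endswith((".gtf", ".gff", ".gff3")):
        return read_genes_gtf(path)
    return read_genes_refgene(path)


def read_states_bed(path: str | Path, strict_vocabulary: bool = True) -> pd.DataFrame:
    """Read a BED4 chromatin-state track (name column = state group).

    Intervals labelled "artifacts" are dropped; unknown labels raise unless
    ``strict_vocabulary`` is off.
    """
    states = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"], dtype={"chrom": str},
    )
    states = states[states["state"].str.lower() != "artifacts"].reset_index(drop=True)
    if strict_vocabulary and len(states):
        unknown = set(states["state"]) - set(CHROMATIN_STATES)
        if unknown:
            raise ValueError(f"unknown chromatin state labels: {sorted(unknown)}")
    return states


def write_states_bed(states: pd.DataFrame, path: str | Path) -> None:
    states[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )
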