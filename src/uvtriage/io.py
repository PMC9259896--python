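"""Readers and writers: VCF (via pysam), PED pedigrees, gene panels, term tables.

VCF conventions
---------------
Genotypes are read from FORMAT ``GT``; depth and allele support from
``DP`` and ``AD`` (per-allele, ref first). If ``AD`` is absent a FORMAT
``AF`` field is accepted directly as the alternate-allele fraction.
Annotations come from INFO keys ``GENE``, ``CSQ_CLASS``, ``TRANSCRIPT``
and ``AF_<db>`` (e.g. ``AF_1KG``, ``AF_EXAC``, ``AF_EVS``); a sidecar TSV
keyed by chrom/pos/ref/alt overrides INFO values, which lets exact
annotations be injected without rewriting the VCF.

Multi-allelic records are decomposed into biallelic keys: each ALT allele
yields its own :class:`~uvtriage.models.VariantKey` and one
:class:`~uvtriage.models.VariantCall` per carrying sample.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .models import (
    Consequence,
    GenePanel,
    Individual,
    Pedigree,
    Sex,
    VariantAnnotation,
    VariantCall,
    VariantKey,
    Zygosity,
)

logger = logging.getLogger(__name__)

_AF_PREFIX = "AF_"


class VcfFormatError(ValueError):
    """Malformed or incomplete VCF content."""


def _zygosity_from_gt(alleles: tuple, alt_index: int) -> Zygosity:
    called = [a for a in alleles if a is not None]
    if len(called) == 1:
        return Zygosity.HEMI
    if all(a == alt_index for a in called):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_vcf(
    path: str | Path,
    annotation_sidecar: Optional[str | Path] = None,
) -> tuple[list[VariantCall], list[VariantAnnotation]]:
    """Read a single- or multi-sample VCF into typed calls and annotations.

    Returns one :class:`VariantCall` per (sample, ALT allele) with a
    non-reference genotype, and one :class:`VariantAnnotation` per
    decomposed biallelic key that carries annotation. Output is sorted by
    variant key (then sample id) regardless of input order.

    Raises
    ------
    VcfFormatError
        If a non-reference genotype lacks both DP/AD and AF, naming the
        sample and position.
    """
    path = Path(path)
    calls: list[VariantCall] = []
    annotations: dict[VariantKey, VariantAnnotation] = {}

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            info = dict(rec.info)
            transcript = str(info.get("TRANSCRIPT", "") or "")
            for alt_index, alt in enumerate(rec.alts, start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt, transcript)
                ann = _annotation_from_info(key, info)
                if ann is not None:
                    annotations[key] = ann
                for sample_name, sample in rec.samples.items():
                    gt = sample.get("GT")
                    if gt is None or all(a in (None, 0) for a in gt):
                        continue
                    if alt_index not in gt:
                        continue
                    dp = sample.get("DP")
                    ad = sample.get("AD")
                    af = sample.get("AF")
                    if dp is not None and ad is not None and ad[alt_index] is not None:
                        if dp == 0:
                            alt_fraction = 0.0
                        else:
                            alt_fraction = ad[alt_index] / dp
                        depth = int(dp)
                    elif af is not None and dp is not None:
                        alt_fraction = float(af[alt_index - 1] if isinstance(af, tuple) else af)
                        depth = int(dp)
                    else:
                        raise VcfFormatError(
                            f"sample {sample_name} at {rec.chrom}:{rec.pos} has a "
                            "non-reference genotype but no DP/AD (or AF) FORMAT values"
                        )
                    calls.append(
                        VariantCall(
                            key=key,
                            sample_id=sample_name,
                            zygosity=_zygosity_from_gt(gt, alt_index),
                            read_depth=depth,
                            alt_fraction=min(1.0, max(0.0, alt_fraction)),
                        )
                    )

    if annotation_sidecar is not None:
        for ann in read_annotation_table(annotation_sidecar):
            annotations[ann.key] = ann  # sidecar wins over INFO

    calls.sort(key=lambda c: (c.key.sort_key, c.sample_id))
    ann_list = sorted(annotations.values(), key=lambda a: a.key.sort_key)
    logger.info("read %d calls, %d annotated keys from %s", len(calls), len(ann_list), path)
    return calls, ann_list


def read_vcf_samples(path: str | Path) -> list[str]:
    """Sample ids declared in a VCF header (all are genotyped at every site)."""
    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.samples)


def _annotation_from_info(key: VariantKey, info: dict) -> Optional[VariantAnnotation]:
    gene = info.get("GENE")
    csq = info.get("CSQ_CLASS")
    if gene is None and csq is None:
        return None
    consequence = Consequence(str(csq)) if csq is not None else Consequence.MISSENSE
    freqs = {}
    for k, v in info.items():
        if k.startswith(_AF_PREFIX):
            # VCF floats are single precision; 6 decimals recovers what was written
            freqs[k[len(_AF_PREFIX):]] = round(float(v[0] if isinstance(v, tuple) else v), 6)
    gene_symbol = "" if consequence is Consequence.INTERGENIC else str(gene or "")
    return VariantAnnotation(
        key=key,
        gene_symbol=gene_symbol,
        consequence=consequence,
        population_freqs=freqs,
    )


def read_annotation_table(path: str | Path) -> list[VariantAnnotation]:
    """Read a sidecar annotation TSV.

    Required columns: chrom, pos, ref, alt, gene, consequence; optional:
    transcript, hgvs_c, hgvs_p, and any number of ``af_<db>`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise VcfFormatError(f"annotation table {path} missing columns: {sorted(missing)}")
    af_cols = [c for c in df.columns if c.lower().startswith("af_")]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = VariantKey(
            str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]),
            str(d.get("transcript", "") or ""),
        )
        freqs = {
            c[3:]: float(d[c]) for c in af_cols if pd.notna(d[c])
        }
        consequence = Consequence(str(d["consequence"]))
        gene = "" if consequence is Consequence.INTERGENIC else str(d["gene"] or "")
        out.append(
            VariantAnnotation(
                key=key,
                gene_symbol=gene,
                consequence=consequence,
                population_freqs=freqs,
                hgvs_c=str(d.get("hgvs_c", "") or ""),
                hgvs_p=str(d.get("hgvs_p", "") or ""),
            )
        )
    return out


def write_vcf(
    path: str | Path,
    calls: Sequence[VariantCall],
    annotations: Iterable[VariantAnnotation] = (),
    samples: Optional[Sequence[str]] = None,
    sample_sexes: Optional[dict[str, Sex]] = None,
    filters: Optional[dict[tuple[VariantKey, str], str]] = None,
) -> None:
    """Write calls (and annotations into INFO) as an uncompressed VCF.

    ``filters`` optionally maps (key, sample_id) to a failed-rule name;
    a record's FILTER is PASS unless every carrier failed, in which case
    the first carrier's first failed rule is recorded.
    """
    path = Path(path)
    ann_by_key = {a.key: a for a in annotations}
    by_key: dict[VariantKey, list[VariantCall]] = {}
    for c in calls:
        by_key.setdefault(c.key, []).append(c)

    if samples is None:
        samples = sorted({c.sample_id for c in calls})

    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=depth,Description="Read depth at or below threshold">')
    header.add_line('##FILTER=<ID=vaf,Description="Alternate-allele fraction below threshold">')
    header.add_line('##FILTER=<ID=popfreq,Description="Population frequency above threshold">')
    header.add_line('##FILTER=<ID=consequence,Description="Excluded consequence class">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">')
    header.add_line('##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Canonical transcript">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    db_names = sorted({db for a in ann_by_key.values() for db in a.population_freqs})
    for db in db_names:
        header.add_line(
            f'##INFO=<ID=AF_{db},Number=1,Type=Float,Description="Population allele frequency ({db})">'
        )
    contigs = []
    for key in sorted(by_key, key=lambda k: k.sort_key):
        if key.chrom not in contigs:
            contigs.append(key.chrom)
    for key in sorted(ann_by_key, key=lambda k: k.sort_key):
        if key.chrom not in contigs:
            contigs.append(key.chrom)
    for contig in contigs:
        header.add_line(f"##contig=<ID={contig}>")
    for s in samples:
        header.add_sample(s)

    keys = sorted(set(by_key) | set(ann_by_key), key=lambda k: k.sort_key)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in keys:
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            ann = ann_by_key.get(key)
            if ann is not None:
                if ann.gene_symbol:
                    rec.info["GENE"] = ann.gene_symbol
                rec.info["CSQ_CLASS"] = ann.consequence.value
                for db, freq in ann.population_freqs.items():
                    rec.info[f"AF_{db}"] = freq
            if key.transcript_id:
                rec.info["TRANSCRIPT"] = key.transcript_id
            key_calls = by_key.get(key, [])
            carrier = {c.sample_id: c for c in key_calls}
            failed = None
            if filters:
                names = [filters.get((key, c.sample_id)) for c in key_calls]
                names = [n for n in names if n]
                if names and len(names) == len(key_calls):
                    failed = names[0]
            rec.filter.add(failed if failed else "PASS")
            for s in samples:
                call = carrier.get(s)
                if call is None:
                    rec.samples[s]["GT"] = (0, 0)
                    continue
                alt_reads = call.alt_reads
                rec.samples[s]["DP"] = call.read_depth
                rec.samples[s]["AD"] = (call.read_depth - alt_reads, alt_reads)
                if call.zygosity is Zygosity.HEMI:
                    rec.samples[s]["GT"] = (1,)
                elif call.zygosity is Zygosity.HOM_ALT:
                    rec.samples[s]["GT"] = (1, 1)
                else:
                    rec.samples[s]["GT"] = (0, 1)
            out.write(rec)
    logger.info("wrote %d records for %d samples to %s", len(keys), len(samples), path)


def read_pedigree(path: str | Path) -> list[Pedigree]:
    """Read a 6-column PED file (family, individual, father, mother, sex, phenotype).

    "0" denotes a missing parent; sex code 1 is male, 2 female, anything
    else unknown; phenotype 2 is affected. A parent id that never appears
    as an individual is kept as a reference (single-parent availability is
    decided by genotype presence, not by the PED), but a parent id both
    dangling and unresolvable elsewhere in the family draws a warning.
    """
    families: dict[str, list[Individual]] = {}
    seen_ids: set[str] = set()
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{line_no}: expected 6 PED columns, got {len(fields)}")
            rows.append((line_no, fields[:6]))

    for line_no, (fam, ind, father, mother, sex_code, pheno) in rows:
        if ind in seen_ids:
            raise ValueError(f"{path}:{line_no}: duplicate individual id {ind!r}")
        seen_ids.add(ind)
        sex = {"1": Sex.MALE, "2": Sex.FEMALE}.get(sex_code, Sex.UNKNOWN)
        families.setdefault(fam, []).append(
            Individual(
                sample_id=ind,
                sex=sex,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                affected=pheno == "2",
            )
        )

    pedigrees = []
    for fam, members in families.items():
        ids = {m.sample_id for m in members}
        for m in members:
            for parent in (m.mother_id, m.father_id):
                if parent is not None and parent not in ids:
                    warnings.warn(
                        f"family {fam}: parent {parent!r} of {m.sample_id} not in pedigree; "
                        "treated as unavailable",
                        stacklevel=2,
                    )
        pedigrees.append(Pedigree(family_id=fam, members=members))
    return pedigrees


def write_pedigree(path: str | Path, pedigrees: Sequence[Pedigree]) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.sample_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code[m.sex],
                            "2" if m.affected else "1",
                        ]
                    )
                    + "\n"
                )


def read_panel(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """Read a gene panel from a TSV with a ``gene`` column (or one symbol per line)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"panel file {path} is empty")
    lines = text.splitlines()
    header = lines[0].split("\t")
    if "gene" in [h.strip().lower() for h in header]:
        col = [h.strip().lower() for h in header].index("gene")
        symbols = [ln.split("\t")[col].strip() for ln in lines[1:] if ln.strip()]
    else:
        symbols = [ln.split("\t")[0].strip() for ln in lines if ln.strip()]
    symbols = [s for s in symbols if s]
    unique = list(dict.fromkeys(symbols))
    if len(unique) < len(symbols):
        warnings.warn(f"panel {path}: {len(symbols) - len(unique)} duplicate symbols removed",
                      stacklevel=2)
    if not unique:
        raise ValueError(f"panel file {path} contains no gene symbols")
    panel = GenePanel(name=name or path.stem, genes=frozenset(unique), provenance=str(path))
    logger.info("panel %s: %d genes", panel.name, len(panel))
    return panel


def read_terms(path: str | Path) -> list[tuple[str, str, frozenset[str]]]:
    """Read term→gene annotations from GMT (term, description, genes...) or
    long-format TSV (term_id, term_name, gene).

    Gene sets are deduplicated; term order follows first appearance.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"term file {path} is empty")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    first = lines[0].split("\t")
    if [h.strip().lower() for h in first[:3]] == ["term_id", "term_name", "gene"]:
        terms: dict[str, tuple[str, list[str]]] = {}
        for ln in lines[1:]:
            term_id, term_name, gene = (f.strip() for f in ln.split("\t")[:3])
            terms.setdefault(term_id, (term_name, []))[1].append(gene)
        return [(tid, name, frozenset(genes)) for tid, (name, genes) in terms.items()]
    out = []
    for ln in lines:
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ValueError(f"term file {path}: GMT line needs >= 3 tab-separated fields: {ln!r}")
        term_id, term_name, genes = fields[0].strip(), fields[1].strip(), fields[2:]
        out.append((term_id, term_name, frozenset(g.strip() for g in genes if g.strip())))
    return out


def write_terms(path: str | Path, terms: Sequence[tuple[str, str, frozenset[str]]]) -> None:
    with open(path, "w") as fh:
        for term_id, term_name, genes in terms:
            fh.write("\t".join([term_id, term_name, *sorted(genes)]) + "\n")


def write_panel(path: str | Path, panel: GenePanel) -> None:
    with open(path, "w") as fh:
        fh.write("gene\n")
        for g in sorted(panel.genes):
            fh.write(g + "\n")
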