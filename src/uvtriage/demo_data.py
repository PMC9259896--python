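"""A bundled demonstration cohort: 147 suspected-ASD probands, 48 of whom
carry reportable findings (53 classified variants in 42 genes).

This curated record set mirrors the shape of a published-style pediatric
ASD exome series: a primary ASD gene panel plus an NDD-extension tier,
heterozygous and X-hemizygous calls, trio-resolved origins (de novo,
maternal, paternal, excluded-in-one-parent, untested), one presumed
compound-heterozygous patient, and a twin pair sharing an identical
frameshift. It serves as the worked example for the yield summary and as
a regression fixture: aggregating these records must reproduce the
cohort-level yield figures stated alongside them.

Genomic coordinates here are schematic placeholders (the triage
arithmetic depends only on key identity); HGVS strings identify the
variants.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

from .acmg import AcmgClass
from .models import Sex, VariantKey, Zygosity
from .segregation import (
    Basis,
    InheritanceCall,
    InheritanceCategory,
    Parent,
)
from .triage import Tier, TriageRecord, YieldSummary, build_yield_summary

#: Cohort demographics: 147 probands, 110 boys and 37 girls.
TOTAL_PATIENTS = 147
N_MALE = 110
N_FEMALE = 37

# patient, sex, gene, hgvs_c, zygosity, origin, class, ndd-extension flag
# origin codes: dn, mat, pat, na (untested), xm (excluded in mother)
_ROWS = [
    ("025244", "F", "ABCA13", "c.8953dup", "het", "na", 4, False),
    ("033532", "M", "ACTL6B", "c.694C>A", "het", "na", 3, False),
    ("021055", "M", "ADNP", "c.2188C>T", "het", "dn", 5, False),
    ("027819", "M", "ADNP", "c.3071_3072del", "het", "na", 4, False),
    ("020213", "F", "ADNP", "c.2496_2499del", "het", "dn", 5, False),
    ("035442", "F", "CAMK2B", "c.328G>A", "het", "na", 4, False),
    ("045750", "F", "CHD8", "c.7181A>G", "het", "na", 3, False),
    ("041619", "M", "CSNK1E", "c.188-1G>T", "het", "na", 4, False),
    ("046526", "M", "CYFIP2", "c.40G>A", "het", "na", 3, True),
    ("040054", "M", "DNMT3A", "c.1969G>A", "het", "xm", 3, False),
    ("025324", "M", "DLG2", "c.285A>G", "het", "dn", 3, False),
    ("016930", "F", "DYRK1A", "c.1316del", "het", "dn", 5, False),
    ("047559", "M", "FGFR2", "c.1069G>T", "het", "pat", 3, True),
    ("047560", "M", "FGFR2", "c.1069G>T", "het", "pat", 3, True),
    ("024441", "M", "FOXP2", "c.1674G>A", "het", "na", 4, False),
    ("039934", "F", "FBXO11", "c.1112G>T", "het", "na", 3, False),
    ("039934", "F", "HECW2", "c.4436G>A", "het", "na", 4, False),
    ("041707", "M", "HECW2", "c.4294-1G>T", "het", "na", 4, False),
    ("035247", "M", "GNE", "c.1287dup", "het", "na", 4, True),
    ("045124", "F", "GRIA1", "c.1526G>A", "het", "dn", 4, False),
    ("045232", "M", "GRIA4", "c.627T>G", "het", "na", 3, True),
    ("046940", "M", "GRIA4", "c.1064A>C", "het", "na", 3, True),
    ("018325", "M", "GRIN2A", "c.982G>T", "het", "na", 4, False),
    ("016906", "M", "GRIN2A", "c.4204C>T", "het", "na", 3, False),
    ("016906", "M", "GRIN2A", "c.2329C>G", "het", "na", 3, False),
    ("027448", "M", "IQSEC2", "c.2563C>T", "hemi", "dn", 5, False),
    ("019020", "M", "KCNK9", "c.392G>A", "het", "dn", 4, True),
    ("019450", "M", "KCNQ2", "c.1997C>T", "het", "na", 3, False),
    ("037249", "M", "KCNQ5", "c.911G>C", "het", "na", 3, False),
    ("033739", "M", "KDM5A", "c.953A>G", "het", "na", 3, False),
    ("040353", "M", "KDM6B", "c.3196_3199dup", "het", "dn", 5, False),
    ("047960", "M", "KMT2C", "c.11586_11587del", "het", "na", 4, False),
    ("029613", "M", "LZTR1", "c.451G>A", "het", "dn", 4, False),
    ("029613", "M", "LZTR1", "c.1672C>T", "het", "mat", 4, False),
    ("037023", "M", "MAGT1", "c.527C>T", "hemi", "mat", 3, True),
    ("033763", "F", "MECP2", "c.961C>T", "het", "dn", 5, False),
    ("018653", "F", "NR4A2", "c.571C>T", "het", "dn", 5, False),
    ("027329", "M", "NRXN3", "c.526C>T", "het", "mat", 4, False),
    ("022629", "M", "PPP2R5D", "c.592G>A", "het", "dn", 5, False),
    ("038924", "F", "PPP2R5D", "c.758G>A", "het", "na", 4, False),
    ("035820", "F", "RAI1", "c.1854del", "het", "dn", 5, False),
    ("036247", "M", "RPS6KA3", "c.1631A>G", "hemi", "na", 4, False),
    ("018960", "F", "SCN8A", "c.57del", "het", "xm", 4, False),
    ("027720", "M", "SIN3B", "c.1843G>A", "het", "dn", 4, False),
    ("034742", "F", "SLC2A1", "c.667C>T", "het", "xm", 5, True),
    ("023509", "F", "SOS2", "c.791C>A", "het", "dn", 5, False),
    ("019146", "F", "STAG1", "c.2672A>C", "het", "na", 3, False),
    ("022940", "M", "TBL1XR1", "c.303_304del", "het", "na", 4, False),
    ("022941", "M", "TBL1XR1", "c.303_304del", "het", "na", 4, False),
    ("040139", "M", "TBL1XR1", "c.1183T>C", "het", "dn", 5, False),
    ("040110", "M", "TM4SF20", "c.184-2A>T", "het", "xm", 3, False),
    ("040110", "M", "KRAS", "c.401C>G", "het", "mat", 4, True),
    ("011139", "M", "TRIP12", "c.4813dup", "het", "dn", 5, False),
]

_X_GENES = frozenset({"IQSEC2", "RPS6KA3", "MAGT1"})

_ORIGIN = {
    "dn": InheritanceCall(InheritanceCategory.DE_NOVO, basis=Basis.TRIO),
    "mat": InheritanceCall(InheritanceCategory.MATERNAL, basis=Basis.TRIO),
    "pat": InheritanceCall(InheritanceCategory.PATERNAL, basis=Basis.TRIO),
    "na": InheritanceCall(InheritanceCategory.NOT_TESTED),
    "xm": InheritanceCall(
        InheritanceCategory.EXCLUDED_ONE_PARENT,
        excluded_parent=Parent.MOTHER,
        basis=Basis.SINGLE_PARENT,
    ),
}

#: Yield figures the demonstration records must reproduce.
EXPECTED_YIELD = {
    "asd_plp": {"n_patients": 30, "pct": 20.4, "n_variants": 31},
    "asd_vus": {"n_patients": 9, "pct": 6.1, "n_variants": 12},
    "ndd_plp": {"n_patients": 4, "pct": 2.7, "n_variants": 4},
    "ndd_vus": {"n_patients": 6, "pct": 4.1, "n_variants": 6},
    "overall_plp": {"n_patients": 34, "pct": 23.1},
    "multi_variant": {"asd_panel": 3, "ndd_extension": 1},
}


def demo_sexes() -> dict[str, Sex]:
    return {row[0]: (Sex.MALE if row[1] == "M" else Sex.FEMALE) for row in _ROWS}


def _keys() -> dict[tuple[str, str], VariantKey]:
    """Deterministic schematic coordinates: one locus per (gene, hgvs_c)."""
    genes = list(dict.fromkeys(row[2] for row in _ROWS))
    gene_index = {g: i for i, g in enumerate(genes)}
    out: dict[tuple[str, str], VariantKey] = {}
    per_gene = Counter()
    for _, _, gene, hgvs, *_ in _ROWS:
        if (gene, hgvs) in out:
            continue
        chrom = "X" if gene in _X_GENES else str(gene_index[gene] % 22 + 1)
        offset = per_gene[gene]
        per_gene[gene] += 1
        out[(gene, hgvs)] = VariantKey(
            chrom=chrom,
            pos=1_000_000 * (gene_index[gene] + 1) + offset,
            ref="A",
            alt="G",
            transcript_id=f"TX_{gene}",
        )
    return out


def bundled_cohort() -> tuple[list[TriageRecord], YieldSummary]:
    """The demonstration triage records and the summary they produce.

    Returns the 53 typed records and ``build_yield_summary(records, 147)``.
    The summary must agree with :data:`EXPECTED_YIELD`.
    """
    keys = _keys()
    gene_distinct = Counter(key.transcript_id for key in set(keys.values()))
    carrier_counts = Counter(keys[(gene, hgvs)] for _, _, gene, hgvs, *_ in _ROWS)

    records = []
    for sample, _sex, gene, hgvs, zyg, origin, klass, ndd in _ROWS:
        key = keys[(gene, hgvs)]
        tier = Tier.NDD_EXTENSION if ndd else Tier.ASD_PANEL
        single = gene_distinct[f"TX_{gene}"] == 1
        carriers = carrier_counts[key]
        records.append(
            TriageRecord(
                sample_id=sample,
                key=key,
                gene_symbol=gene,
                acmg_class=AcmgClass(klass, "as_reported"),
                tier=tier,
                single_event=single,
                ultrarare=carriers == 1,
                inheritance=_ORIGIN[origin],
                zygosity=Zygosity.HEMI if zyg == "hemi" else Zygosity.HET,
            )
        )

    # the presumed compound-het pair: one de novo + one maternal LZTR1 variant
    lztr1 = [r for r in records if r.gene_symbol == "LZTR1"]
    a, b = lztr1
    records = [
        dataclasses.replace(r, compound_het_partner=(b if r is a else a).key)
        if r in (a, b)
        else r
        for r in records
    ]

    summary = build_yield_summary(records, TOTAL_PATIENTS)
    return records, summary
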