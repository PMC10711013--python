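"""Tumour-content inference, resistance triage, SV region flags and cohort
summaries.

Tumour purity is inferred from the TP53 variant allele fraction: TP53
mutation is a near-ubiquitous, early, clonal event in high grade serous
ovarian carcinoma, so under a diploid heterozygous model purity = 2 x VAF
(capped at 1), and under loss-of-heterozygosity purity = 2v / (1 + v).

Non-BRCA panel variants are triaged into resistance categories with an
explicit, config-overridable ruleset standing in for manual review:
truncating or deleterious-missense hits in the Shieldin/53BP1 axis on a
BRCA1-mutant background are "potential" resistance mechanisms (their loss
restores homologous recombination in BRCA1-deficient cells); damaging hits
in other panel genes are "tenuous"; confirmed reversions are "definitive".
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, ContractError
from .variants import SeqVariant

__all__ = [
    "PurityEstimate",
    "TriageRecord",
    "CohortSummary",
    "estimate_purity",
    "triage_variant",
    "flag_sv_regions",
    "summarize_cohort",
    "load_candidate_fixture",
    "load_cohort_meta",
    "DEFAULT_GENE_ROLES",
    "DEFAULT_RULESET",
]

# Pathway roles for the capture panel. The Shieldin/53BP1 axis promotes
# NHEJ; its loss in BRCA1-mutant cells restores HR and confers PARPi
# resistance.
DEFAULT_GENE_ROLES: dict[str, str] = {
    **{g: "shieldin_axis" for g in ("SHLD1", "SHLD2", "SHLD3", "TP53BP1", "RIF1", "MAD2L2")},
    **{g: "hr_other" for g in (
        "BRCA1", "BRCA2", "RAD51", "RAD51B", "RAD51C", "RAD51D", "XRCC2", "XRCC3",
        "PALB2", "BRIP1", "BARD1", "ATM", "ATR", "CHEK1", "CHEK2", "MRE11", "NBN",
        "RAD50", "FANCA", "FANCD2", "TP53",
    )},
    "ABCB1": "efflux",
    **{g: "other" for g in ("ARID1A", "PARP1", "PARP2", "TRIP13", "SMARCA4")},
}

TRUNCATING = {"stop_gained", "frameshift_variant", "stop_lost", "start_lost"}

DEFAULT_RULESET: dict = {
    "sift_deleterious_max": 0.05,
    "polyphen_damaging_min": 0.85,
    "shieldin_requires_context": "BRCA1",
}


@dataclass(frozen=True)
class PurityEstimate:
    """TP53-VAF-derived tumour content. ``purity`` is None when no TP53
    variant with a defined VAF was available (undefined, not zero)."""

    tp53_vaf: float | None
    mode: str
    purity: float | None
    capped: bool = False

    @property
    def defined(self) -> bool:
        return self.purity is not None


def estimate_purity(tp53_variants: Sequence[SeqVariant], mode: str = "het_diploid") -> PurityEstimate:
    """Infer tumour content from TP53 VAF under a clonal copy model.

    With several TP53 variants the maximum VAF is used (clonal assumption).
    ``het_diploid``: purity = min(1, 2v); ``loh``: purity = 2v / (1 + v).
    """
    if mode not in ("het_diploid", "loh"):
        raise ConfigError(f"unknown purity mode: {mode}")
    vafs = [v.vaf for v in tp53_variants if v.vaf is not None]
    if not vafs:
        return PurityEstimate(tp53_vaf=None, mode=mode, purity=None)
    vaf = max(vafs)
    if mode == "het_diploid":
        raw = 2.0 * vaf
    else:
        raw = 2.0 * vaf / (1.0 + vaf)
    capped = raw > 1.0
    return PurityEstimate(tp53_vaf=vaf, mode=mode, purity=min(raw, 1.0), capped=capped)


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriageRecord:
    patient_id: str
    sample_type: str  # pre_parpi / post_parpi
    brca_context: str  # BRCA1 / BRCA2 / wildtype / unknown
    gene: str
    consequence: str
    hgvs_p: str = ""
    vaf: float | None = None
    sift_score: float | None = None
    polyphen_score: float | None = None
    is_confirmed_reversion: bool = False
    category: str = ""


def triage_variant(
    rec: TriageRecord,
    gene_roles: Mapping[str, str] | None = None,
    ruleset: Mapping | None = None,
) -> TriageRecord:
    """Assign a resistance category to one candidate variant.

    Default rules, applied in order:

    1. confirmed reversion -> ``definitive``
    2. truncating variant in a Shieldin-axis gene on a BRCA1 background
       -> ``potential``
    3. Shieldin-axis missense with SIFT <= 0.05 or PolyPhen >= 0.85 on a
       BRCA1 background -> ``potential``
    4. truncating or deleterious missense in any other panel gene
       -> ``tenuous``
    5. otherwise ``not_resistance``
    """
    roles = dict(DEFAULT_GENE_ROLES if gene_roles is None else gene_roles)
    rules = dict(DEFAULT_RULESET)
    if ruleset:
        rules.update(ruleset)
    if rec.gene not in roles:
        raise ConfigError(f"gene not in panel role config: {rec.gene}")
    role = roles[rec.gene]
    truncating = rec.consequence in TRUNCATING
    deleterious_missense = rec.consequence == "missense_variant" and (
        (rec.sift_score is not None and rec.sift_score <= rules["sift_deleterious_max"])
        or (rec.polyphen_score is not None and rec.polyphen_score >= rules["polyphen_damaging_min"])
    )
    if rec.is_confirmed_reversion:
        cat = "definitive"
    elif (
        role == "shieldin_axis"
        and rec.brca_context == rules["shieldin_requires_context"]
        and (truncating or deleterious_missense)
    ):
        cat = "potential"
    elif truncating or deleterious_missense:
        cat = "tenuous"
    else:
        cat = "not_resistance"
    return replace(rec, category=cat)


# ---------------------------------------------------------------------------
# SV region flags
# ---------------------------------------------------------------------------

def flag_sv_regions(
    sv_breakpoints: Sequence[tuple[str, int]],
    regions: Mapping[str, tuple[str, int, int]],
) -> list[dict]:
    """Flag breakpoints falling in configured regions of interest.

    ``regions`` maps a name (e.g. ``ABCB1_intron1``) to ``(contig, start,
    end)``, 1-based inclusive. Returns one flag dict per (breakpoint,
    region) hit.
    """
    flags: list[dict] = []
    for contig, pos in sv_breakpoints:
        for name, (rc, rs, re_) in regions.items():
            if contig == rc and rs <= pos <= re_:
                flags.append({"region": name, "contig": contig, "pos": pos})
    return flags


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_brca_mutant: int
    n_reversion_patients: int
    reversion_prevalence_pct: int | None
    n_potential_patients: int
    n_potential_genes: int
    category_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_brca_mutant": self.n_brca_mutant,
            "n_reversion_patients": self.n_reversion_patients,
            "reversion_prevalence_pct": self.reversion_prevalence_pct,
            "n_potential_patients": self.n_potential_patients,
            "n_potential_genes": self.n_potential_genes,
            "category_counts": self.category_counts,
        }


def summarize_cohort(
    triage: Sequence[TriageRecord],
    reversions_by_patient: Mapping[str, Sequence] | None = None,
    cohort_meta: Mapping | None = None,
) -> CohortSummary:
    """Distinct-patient / distinct-gene counts per resistance category.

    Reversion prevalence uses the BRCA-mutant patients as denominator
    (only they can revert) and rounds to the nearest whole percent. With a
    zero denominator the prevalence is undefined (None), never zero.
    """
    meta = dict(cohort_meta or {})
    reversions_by_patient = {
        k: v for k, v in (reversions_by_patient or {}).items() if len(v) > 0
    }
    rev_patients = set(reversions_by_patient)
    n_rev = meta.get("n_reversion_patients", len(rev_patients))
    n_patients = meta.get("n_patients", len({t.patient_id for t in triage} | rev_patients))
    n_brca = meta.get("n_brca_mutant", 0)
    prevalence = round(100.0 * n_rev / n_brca) if n_brca else None
    potential = [t for t in triage if t.category == "potential"]
    cats: dict[str, dict] = {}
    for cat in ("definitive", "potential", "tenuous", "not_resistance"):
        rows = [t for t in triage if t.category == cat]
        cats[cat] = {
            "n_records": len(rows),
            "n_patients": len({t.patient_id for t in rows}),
            "n_genes": len({t.gene for t in rows}),
        }
    return CohortSummary(
        n_patients=int(n_patients),
        n_brca_mutant=int(n_brca),
        n_reversion_patients=int(n_rev),
        reversion_prevalence_pct=prevalence,
        n_potential_patients=len({t.patient_id for t in potential}),
        n_potential_genes=len({t.gene for t in potential}),
        category_counts=cats,
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("revertscan").joinpath("data", name)))


def load_candidate_fixture() -> list[TriageRecord]:
    """Curated post-PARPi candidate resistance variants from a 26-patient
    HGSC cohort, with categories as assigned by the original review."""
    df = pd.read_csv(_data_path("panel_candidate_variants.tsv"), sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        out.append(
            TriageRecord(
                patient_id=r["patient_id"],
                sample_type=r["sample_type"],
                brca_context=r["brca_context"],
                gene=r["gene"],
                consequence=r["consequence"],
                hgvs_p=r["hgvs_p"],
                vaf=float(r["vaf"]),
                category=r["category"],
            )
        )
    return out


def load_cohort_meta() -> dict:
    """Headline counts for the study cohort (sizes, BRCA status, TP53 VAF)."""
    return yaml.safe_load(_data_path("hgsc_cohort.yaml").read_text())


def triage_to_frame(records: Iterable[TriageRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
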