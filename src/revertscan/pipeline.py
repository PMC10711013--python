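"""End-to-end orchestration: merge -> subtract -> revert -> curate -> summarize.

File-based entry points wrap the in-memory :func:`analyse_patient`; both are
deterministic given a seed and write byte-stable report bundles (reversion
TSV/VCF, purity JSON, audit TSV, cohort summary JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .curation import PurityEstimate, estimate_purity, summarize_cohort
from .errors import ConfigError, ReferenceMismatchError
from .refmodel import GeneModel, load_gene_model, write_gene_model
from .reads import AlignedRead, read_sam
from .reversion import PrimaryLesion, ReversionCall, call_reversions, is_inverse
from .variants import (
    SeqVariant,
    consensus_merge,
    normalize_variant,
    parse_caller_vcf,
    subtract_germline,
    write_vcf,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "analyse_patient", "run_pipeline", "export_lollipop_data",
           "load_primary_lesion", "write_primary_lesion"]


# ---------------------------------------------------------------------------
# Lesion config I/O
# ---------------------------------------------------------------------------

def load_primary_lesion(path: str | Path) -> PrimaryLesion:
    cfg = yaml.safe_load(Path(path).read_text())
    for key in ("gene", "contig", "pos", "ref", "alt"):
        if key not in cfg:
            raise ConfigError(f"lesion config missing required field: {key}")
    v = SeqVariant(str(cfg["contig"]), int(cfg["pos"]), str(cfg["ref"]).upper(), str(cfg["alt"]).upper())
    return PrimaryLesion(
        gene=str(cfg["gene"]),
        variant=v,
        origin=str(cfg.get("origin", "unknown")),
        hgvs_c=str(cfg.get("hgvs_c", "")),
        hgvs_p=str(cfg.get("hgvs_p", "")),
    )


def write_primary_lesion(lesion: PrimaryLesion, path: str | Path) -> None:
    v = lesion.variant
    doc = {
        "gene": lesion.gene,
        "contig": v.contig,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "origin": lesion.origin,
        "hgvs_c": lesion.hgvs_c,
        "hgvs_p": lesion.hgvs_p,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# In-memory patient analysis
# ---------------------------------------------------------------------------

def _normalize_list(model: GeneModel, variants: Sequence[SeqVariant], primary: SeqVariant) -> list[SeqVariant]:
    """Normalize caller output against the model reference.

    Records on other contigs pass through untouched; a record whose REF
    disagrees with the reference is kept verbatim only when it is the exact
    restoring allele of the primary lesion (expressed in mutant space),
    otherwise it is dropped with a log message.
    """
    out: list[SeqVariant] = []
    for v in variants:
        if v.contig != model.contig:
            out.append(v)
            continue
        try:
            out.append(normalize_variant(model, v))
        except ReferenceMismatchError:
            if is_inverse(primary, v):
                out.append(v)
            else:
                logger.warning("dropping reference-mismatched record %s", v)
    return out


def analyse_patient(
    model: GeneModel,
    primary: PrimaryLesion,
    caller_lists: Sequence[Sequence[SeqVariant]],
    germline: Sequence[SeqVariant] | None,
    reads: Sequence[AlignedRead] | None,
    min_callers: int | None = None,
    window: int = 200,
    min_shared: int = 2,
    tp53_contig: str = "TP53",
    purity_mode: str = "het_diploid",
    audit_log: list | None = None,
) -> dict:
    """Run consensus, germline subtraction, purity and the reversion screen.

    ``min_callers`` defaults to 2 in matched mode (germline supplied) and 1
    in tumour-only mode. Returns a dict with the somatic list, the purity
    estimate and the reported reversion calls.
    """
    if min_callers is None:
        min_callers = 2 if germline is not None else 1
    norm_primary = (
        normalize_variant(model, primary.variant)
        if primary.variant.contig == model.contig
        else primary.variant
    )
    primary = dataclasses.replace(primary, variant=norm_primary)
    norm_lists = [_normalize_list(model, lst, norm_primary) for lst in caller_lists]
    merged = consensus_merge(norm_lists, min_callers=min_callers)
    if germline is not None:
        germ_norm = _normalize_list(model, germline, norm_primary)
        somatic = subtract_germline(merged, germ_norm)
    else:
        somatic = [v.replace(origin="unknown") for v in merged]
    tp53 = [v for v in somatic + list(merged) if v.contig == tp53_contig]
    purity = estimate_purity(tp53, mode=purity_mode)
    reversions = call_reversions(
        primary,
        [v for v in somatic if v.contig == model.contig],
        reads,
        model,
        window=window,
        min_shared=min_shared,
        audit_log=audit_log,
    )
    return {
        "primary": primary,
        "n_merged": len(merged),
        "somatic": somatic,
        "purity": purity,
        "reversions": reversions,
    }


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    model_path: Path
    lesion_path: Path
    tumour_vcfs: tuple[Path, ...]
    sam_path: Path | None
    outdir: Path
    germline_vcfs: tuple[Path, ...] = ()
    mode: str = "matched"  # matched / tumour_only
    min_callers: int | None = None
    window: int = 200
    min_shared: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("matched", "tumour_only"):
            raise ConfigError(f"mode must be matched or tumour_only: {self.mode}")
        if self.mode == "matched" and not self.germline_vcfs:
            raise ConfigError("matched mode requires germline VCFs")
        for p in (self.model_path, self.lesion_path, *self.tumour_vcfs, *self.germline_vcfs):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.sam_path is not None and not Path(self.sam_path).exists():
            raise ConfigError(f"input path does not exist: {self.sam_path}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full per-patient pipeline and write the report bundle."""
    model = load_gene_model(cfg.model_path)
    primary = load_primary_lesion(cfg.lesion_path)
    caller_lists = [
        parse_caller_vcf(p, caller_id=Path(p).stem.split(".")[-1]) for p in cfg.tumour_vcfs
    ]
    germline = None
    if cfg.mode == "matched":
        germline = [v for p in cfg.germline_vcfs for v in parse_caller_vcf(p, "germline")]
    reads = read_sam(cfg.sam_path) if cfg.sam_path else None
    audit: list[ReversionCall] = []
    min_callers = cfg.min_callers
    if cfg.mode == "tumour_only" and min_callers is None:
        min_callers = 1
    result = analyse_patient(
        model,
        primary,
        caller_lists,
        germline,
        reads,
        min_callers=min_callers,
        window=cfg.window,
        min_shared=cfg.min_shared,
        audit_log=audit,
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_reversion_report(result["reversions"], outdir / "reversions.tsv")
    _write_reversion_report(audit, outdir / "reversions.audit.tsv")
    rev_alleles = [ev for c in result["reversions"] for ev in c.secondary_events]
    write_vcf(rev_alleles, outdir / "reversions.vcf", model.contig, len(model.ref_seq))
    purity: PurityEstimate = result["purity"]
    (outdir / "purity.json").write_text(
        json.dumps(
            {
                "tp53_vaf": purity.tp53_vaf,
                "mode": purity.mode,
                "purity": purity.purity,
                "capped": purity.capped,
            },
            indent=2,
            sort_keys=True,
        )
    )
    stage_log = {
        "n_caller_lists": len(caller_lists),
        "n_caller_records": [len(l) for l in caller_lists],
        "n_consensus": result["n_merged"],
        "n_somatic": len(result["somatic"]),
        "n_reversions_reported": len(result["reversions"]),
        "n_reversions_audited": len(audit),
        "mode": cfg.mode,
        "seed": cfg.seed,
    }
    (outdir / "stages.json").write_text(json.dumps(stage_log, indent=2, sort_keys=True))
    return result


def _write_reversion_report(calls: Sequence[ReversionCall], path: Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.primary.gene,
                "primary": str(c.primary.variant),
                "primary_hgvs_c": c.primary.hgvs_c,
                "secondary": ";".join(str(v) for v in c.secondary_events) or ".",
                "mechanism": c.mechanism,
                "phase": c.phase,
                "shared_reads": c.shared_reads,
                "vaf": "" if c.vaf is None else f"{c.vaf:.6f}",
                "tier": c.tier,
            }
        )
    cols = ["gene", "primary", "primary_hgvs_c", "secondary", "mechanism", "phase",
            "shared_reads", "vaf", "tier"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Lollipop export
# ---------------------------------------------------------------------------

_HGVS_P = re.compile(r"^p\.([A-Za-z]{3})(\d+)(.*)$")


def classify_hgvs_p(hgvs_p: str) -> tuple[int | None, str]:
    """Protein position and mutation type from a p. annotation."""
    m = _HGVS_P.match(hgvs_p or "")
    if not m:
        return None, "unparsed"
    pos = int(m.group(2))
    rest = m.group(3)
    if "fs" in rest:
        return pos, "frameshift"
    if rest.startswith("Ter") or rest == "*":
        return pos, "nonsense"
    if rest == "=":
        return pos, "synonymous"
    if re.fullmatch(r"[A-Za-z]{3}", rest):
        return pos, "missense"
    if rest.startswith("del") or rest.startswith("dup"):
        return pos, "inframe_indel"
    return pos, "other"


def export_lollipop_data(records: Sequence[Mapping], model: GeneModel | None = None) -> pd.DataFrame:
    """One row per distinct protein change with patient count and type.

    ``records`` are mappings with ``hgvs_p`` and ``patient_id``. When a
    model is supplied, positions beyond its protein length are rejected.
    """
    if model is not None:
        protein_len = sum(e - s + 1 for s, e in model.cds_intervals) // 3 - 1
    rows: dict[str, dict] = {}
    for rec in records:
        hgvs = rec.get("hgvs_p", "")
        if not hgvs:
            continue
        pos, mtype = classify_hgvs_p(hgvs)
        if pos is None:
            continue
        if model is not None and pos > protein_len:
            raise ConfigError(f"protein position {pos} beyond protein length {protein_len}")
        row = rows.setdefault(hgvs, {"hgvs_p": hgvs, "protein_position": pos,
                                     "mutation_type": mtype, "patients": set()})
        row["patients"].add(rec.get("patient_id"))
    out = [
        {
            "hgvs_p": r["hgvs_p"],
            "protein_position": r["protein_position"],
            "mutation_type": r["mutation_type"],
            "patient_count": len(r["patients"]),
        }
        for r in sorted(rows.values(), key=lambda r: (r["protein_position"], r["hgvs_p"]))
    ]
    return pd.DataFrame(out, columns=["hgvs_p", "protein_position", "mutation_type", "patient_count"])
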