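"""Tables, VCF, configuration, and the end-to-end pipeline driver.

File contracts:

* phenotype TSV — one row per animal-week:
  ``animal_id line family generation genotype_mecp2 age_days clasping
  tremor activity body_condition muscle_tone weight_g`` (missing ordinal
  values written as ``NA``);
* survival TSV — ``animal_id survival_days censored`` (censored in {0,1});
* genotype TSV — ``animal_id line`` plus one 0/1 column per candidate
  locus;
* variants — VCF 4.2 with ``GENE``, ``LINE``, ``CSQ``, ``PRED`` INFO
  fields (multi-allelic records are split into biallelic variants);
* configuration — YAML with ``inputs``, ``rules``, ``null``, ``scan``
  sections.

Schema violations raise :class:`SchemaError` naming file, line, and
column.  ``run_pipeline`` ties scoring, segregation testing, spectrum
summarization, and per-line association into one deterministic run that
emits JSON/TSV reports plus a manifest (config snapshot, input
checksums, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import __version__
from .association import scan_line
from .mendelian import (
    FamilyCount,
    LineSegregation,
    MendelianNull,
    segregation_test,
)
from .scoring import (
    SUBJECTIVE_PARAMETERS,
    DEFAULT_RULES,
    HealthAssessment,
    ImprovementRules,
    InvalidInputError,
    assessment_nearest_age,
    classify_offspring_improved,
    score_body_weight,
)
from .simulate import SimLine
from .variants import Variant, summarize_spectrum

logger = logging.getLogger("enuscreen")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s", defaults={"stage": "-"}))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


PHENOTYPE_COLUMNS = [
    "animal_id", "line", "family", "generation", "genotype_mecp2", "age_days",
    *SUBJECTIVE_PARAMETERS, "weight_g",
]
SURVIVAL_COLUMNS = ["animal_id", "survival_days", "censored"]


class SchemaError(ValueError):
    """A malformed input file; names the file, line, and column."""

    def __init__(self, path, line: Optional[int], column: str, message: str):
        self.path, self.line, self.column = str(path), line, column
        loc = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{loc}, column {column!r}: {message}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(path, 1, missing[0], "missing required column")


def read_phenotypes(path) -> pd.DataFrame:
    """Validated per-animal-week phenotype table (``NA`` ordinals -> NaN)."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "line": str, "family": str})
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    for col in [*SUBJECTIVE_PARAMETERS, "genotype_mecp2"]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad_parse = df[col].notna() & values.isna()
        if bad_parse.any():
            i = int(np.flatnonzero(bad_parse)[0])
            raise SchemaError(path, i + 2, col, f"non-numeric value {df[col].iloc[i]!r}")
        allowed = (0, 1) if col == "genotype_mecp2" else (0, 1, 2)
        bad = values.notna() & ~values.isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                path, i + 2, col, f"value {values.iloc[i]} not in {allowed}"
            )
        df[col] = values
    df["age_days"] = pd.to_numeric(df["age_days"], errors="coerce")
    if df["age_days"].isna().any() or (df["age_days"] < 0).any():
        i = int(np.flatnonzero(df["age_days"].isna() | (df["age_days"] < 0))[0])
        raise SchemaError(path, i + 2, "age_days", "must be a non-negative integer")
    df["weight_g"] = pd.to_numeric(df["weight_g"], errors="coerce")
    bad = df["weight_g"].notna() & (df["weight_g"] <= 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise SchemaError(path, i + 2, "weight_g", "must be positive")
    return df


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    _require_columns(df, SURVIVAL_COLUMNS, path)
    df["survival_days"] = pd.to_numeric(df["survival_days"], errors="coerce")
    bad = df["survival_days"].isna() | (df["survival_days"] < 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise SchemaError(path, i + 2, "survival_days", "must be a non-negative number")
    if not df["censored"].isin((0, 1)).all():
        i = int(np.flatnonzero(~df["censored"].isin((0, 1)))[0])
        raise SchemaError(path, i + 2, "censored", "must be 0 or 1")
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Carrier table: animal_id, line, then one 0/1 column per locus."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "line": str})
    _require_columns(df, ["animal_id", "line"], path)
    for col in [c for c in df.columns if c not in ("animal_id", "line")]:
        if not df[col].isin((0, 1)).all():
            i = int(np.flatnonzero(~df[col].isin((0, 1)))[0])
            raise SchemaError(path, i + 2, col, "carrier status must be 0 or 1")
    return df


def genotype_loci(genotypes: pd.DataFrame) -> List[str]:
    return [c for c in genotypes.columns if c not in ("animal_id", "line")]


def read_variants(path) -> List[Variant]:
    """Variants from a VCF 4.2 file; multi-allelic records are split."""
    out: List[Variant] = []
    for record in VCF(str(path)):
        for alt in record.ALT:
            out.append(
                Variant(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    gene=record.INFO.get("GENE") or "",
                    line=record.INFO.get("LINE") or "",
                    consequence=record.INFO.get("CSQ"),
                    prediction=record.INFO.get("PRED") or "unknown",
                )
            )
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_phenotypes(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(variants: Sequence[Variant], path) -> None:
    """Minimal sorted VCF 4.2 with GENE/LINE/CSQ/PRED INFO fields."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
    contigs = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for field_, desc in (
            ("GENE", "Gene symbol"),
            ("LINE", "Founder line"),
            ("CSQ", "Predicted consequence"),
            ("PRED", "Tolerance prediction"),
        ):
            fh.write(
                f'##INFO=<ID={field_},Number=1,Type=String,Description="{desc}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = ";".join(
                f"{k}={x}"
                for k, x in (
                    ("GENE", v.gene), ("LINE", v.line),
                    ("CSQ", v.consequence), ("PRED", v.prediction),
                )
                if x
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info or '.'}\n"
            )


def _truth_payload(line: SimLine) -> dict:
    truth = line.truth
    return {
        "line": line.founder.line,
        "loci": list(truth.loci),
        "latent_effects": dict(truth.latent_effects),
        "survival_log_acceleration": dict(truth.survival_log_acceleration),
        "interaction_latent": {
            "|".join(sorted(k)): v for k, v in truth.interaction_latent.items()
        },
        "interaction_survival": {
            "|".join(sorted(k)): v for k, v in truth.interaction_survival.items()
        },
        "linkage": {"|".join(sorted(k)): v for k, v in truth.linkage.items()},
        "architecture": truth.architecture,
    }


def write_screen(
    lines: Sequence[SimLine],
    outdir,
    variants: Optional[Mapping[str, Sequence[Variant]]] = None,
) -> Dict[str, Path]:
    """Write a simulated screen as phenotype/genotype/survival TSVs + VCF + truth.

    The emitted files round-trip losslessly through the readers above.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phen_rows, surv_rows, geno_rows = [], [], []
    loci = sorted({l for line in lines for l in line.truth.loci})
    for line in lines:
        for animal in line.all_animals:
            geno_rows.append(
                {
                    "animal_id": animal.animal_id,
                    "line": animal.line,
                    **{l: int(animal.carrier_flags.get(l, False)) for l in loci},
                }
            )
            if animal.survival_days is not None:
                surv_rows.append(
                    {
                        "animal_id": animal.animal_id,
                        "survival_days": animal.survival_days,
                        "censored": int(animal.censored),
                    }
                )
            for a in animal.assessments:
                phen_rows.append(
                    {
                        "animal_id": animal.animal_id,
                        "line": animal.line,
                        "family": animal.family,
                        "generation": animal.generation,
                        "genotype_mecp2": int(animal.mecp2_null),
                        "age_days": a.age_days,
                        **{p: getattr(a, p) for p in SUBJECTIVE_PARAMETERS},
                        "weight_g": a.body_weight_g,
                    }
                )
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "truth.json",
    }
    write_phenotypes(pd.DataFrame(phen_rows, columns=PHENOTYPE_COLUMNS), paths["phenotypes"])
    pd.DataFrame(geno_rows).to_csv(paths["genotypes"], sep="\t", index=False)
    pd.DataFrame(surv_rows, columns=SURVIVAL_COLUMNS).to_csv(
        paths["survival"], sep="\t", index=False
    )
    with open(paths["truth"], "w") as fh:
        json.dump([_truth_payload(line) for line in lines], fh, indent=2, sort_keys=True)
        fh.write("\n")
    if variants is not None:
        paths["variants"] = outdir / "variants.vcf"
        write_vcf([v for vs in variants.values() for v in vs], paths["variants"])
    return paths


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    phenotypes: str
    genotypes: str
    survival: str
    variants: Optional[str] = None
    screen: int = 2
    rules: ImprovementRules = field(default_factory=ImprovementRules)
    null: MendelianNull = field(default_factory=MendelianNull)
    alpha: float = 0.05
    bh: bool = False
    mc_reps: int = 100_000
    max_configs: int = 10**7
    seed: int = 0
    output_dir: str = "results"


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    inputs = raw.get("inputs", {})
    scan = raw.get("scan", {})
    return PipelineConfig(
        phenotypes=inputs.get("phenotypes", ""),
        genotypes=inputs.get("genotypes", ""),
        survival=inputs.get("survival", ""),
        variants=inputs.get("variants"),
        screen=int(raw.get("screen", 2)),
        rules=ImprovementRules(**raw.get("rules", {})),
        null=MendelianNull(**raw.get("null", {})),
        alpha=float(scan.get("alpha", 0.05)),
        bh=bool(scan.get("bh", False)),
        mc_reps=int(scan.get("mc_reps", 100_000)),
        max_configs=int(scan.get("max_configs", 10**7)),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "results")),
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    snap["rules"] = asdict(config.rules)
    snap["null"] = asdict(config.null)
    return snap


# ---------------------------------------------------------------------------
# scoring tables and the full pipeline
# ---------------------------------------------------------------------------


def per_animal_table(
    phenotypes: pd.DataFrame,
    survival: Optional[pd.DataFrame] = None,
    rules: ImprovementRules = DEFAULT_RULES,
    screen: int = 2,
) -> pd.DataFrame:
    """Collapse animal-weeks to one row per animal at the assessment age.

    Takes each animal's assessment nearest to the rules' assessment age
    (8 wk), computes the composite score, merges survival, and classifies
    Mecp2/Y animals as improved under the given screen's rules.  Missing
    subjective scores are imputed as 0 (flagged in ``n_imputed``).
    """
    target_age = rules.founder_assessment_age_weeks * 7
    rows = []
    for animal_id, grp in phenotypes.groupby("animal_id", sort=True):
        assessments = []
        for _, r in grp.iterrows():
            if pd.isna(r["weight_g"]):
                continue
            scores = {
                p: (0 if pd.isna(r[p]) else int(r[p])) for p in SUBJECTIVE_PARAMETERS
            }
            imputed = tuple(p for p in SUBJECTIVE_PARAMETERS if pd.isna(r[p]))
            assessments.append(
                HealthAssessment(
                    animal_id=str(animal_id),
                    age_days=int(r["age_days"]),
                    body_weight_g=float(r["weight_g"]),
                    imputed_parameters=imputed,
                    **scores,
                )
            )
        chosen = assessment_nearest_age(assessments, target_age)
        first = grp.iloc[0]
        row = {
            "animal_id": str(animal_id),
            "line": first["line"],
            "family": first["family"],
            "generation": first["generation"],
            "mecp2_null": bool(first["genotype_mecp2"]),
        }
        if chosen is not None:
            row.update(
                {p: getattr(chosen, p) for p in SUBJECTIVE_PARAMETERS},
                weight_g=chosen.body_weight_g,
                weight_score=score_body_weight(chosen.body_weight_g),
                score_total=sum(chosen.subjective_scores)
                + score_body_weight(chosen.body_weight_g),
                assessment_age_days=chosen.age_days,
                n_imputed=len(chosen.imputed_parameters),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if survival is not None:
        table = table.merge(
            survival[SURVIVAL_COLUMNS], on="animal_id", how="left", validate="1:1"
        )
        table["event"] = 1 - table["censored"]
        improved = []
        for _, r in table.iterrows():
            if not r["mecp2_null"] or pd.isna(r.get("survival_days")):
                improved.append(np.nan)
                continue
            score = r.get("score_total")
            improved.append(
                float(
                    classify_offspring_improved(
                        screen=screen,
                        survival_days=int(r["survival_days"]),
                        censored=bool(r["censored"]),
                        score_at_8wk=None if pd.isna(score) else int(score),
                        rules=rules,
                    )
                )
            )
        table["improved"] = improved
    return table


def segregation_by_line(
    animals: pd.DataFrame,
    null: MendelianNull,
    mc_reps: int = 100_000,
    max_configs: int = 10**7,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-line Mendelian segregation tests from classified N3 animals."""
    rows = []
    n3 = animals[
        (animals["generation"] == "N3")
        & animals["mecp2_null"]
        & animals["improved"].notna()
    ]
    for line_id, grp in n3.groupby("line", sort=True):
        families = [
            FamilyCount(len(fam), int(fam["improved"].sum()))
            for _, fam in grp.groupby("family", sort=True)
        ]
        seg = LineSegregation(line_id=str(line_id), families=tuple(families))
        result = segregation_test(
            seg, null, max_configs=max_configs, mc_reps=mc_reps, seed=seed
        )
        rows.append(
            {
                "line": line_id,
                "n_families": len(families),
                "n_offspring": sum(f.n_offspring for f in families),
                "n_improved": sum(f.n_improved for f in families),
                "p_value": result.p_value,
                "method": result.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["line", "n_families", "n_offspring", "n_improved", "p_value", "method"],
    )


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> Path:
    """Score, test segregation, summarize variants, scan associations.

    Deterministic given the config seed; writes JSON/TSV reports and a
    manifest to the output directory and returns its path.
    """
    out = Path(outdir if outdir is not None else config.output_dir)
    for name in ("phenotypes", "genotypes", "survival"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p!r}")
    if config.variants and not Path(config.variants).exists():
        raise FileNotFoundError(f"variants file not found: {config.variants!r}")

    _log("read", f"reading inputs for screen {config.screen}")
    phenotypes = read_phenotypes(config.phenotypes)
    genotypes = read_genotypes(config.genotypes)
    survival = read_survival(config.survival)

    _log("score", "collapsing animal-weeks and classifying improvement")
    animals = per_animal_table(
        phenotypes, survival, rules=config.rules, screen=config.screen
    )

    _log("mendelian", "testing Mendelian segregation per line")
    segregation = segregation_by_line(
        animals,
        config.null,
        mc_reps=config.mc_reps,
        max_configs=config.max_configs,
        seed=config.seed,
    )

    spectrum = None
    if config.variants:
        _log("variants", "summarizing variant spectrum")
        spectrum = summarize_spectrum(read_variants(config.variants))

    _log("associate", "per-line marginal and interaction scans")
    loci = genotype_loci(genotypes)
    scan_tables, km_rows, skipped = [], [], []
    merged = animals.merge(genotypes.drop(columns=["line"]), on="animal_id", how="left")
    n3 = merged[(merged["generation"] == "N3") & merged["mecp2_null"]]
    for line_id, grp in n3.groupby("line", sort=True):
        result = scan_line(
            grp,
            loci=loci,
            ordinal_traits=["score_total", *SUBJECTIVE_PARAMETERS],
            linear_traits=["weight_g"],
            survival_cols=("survival_days", "event"),
            bh=config.bh,
        )
        for kind, df in (("marginal", result.marginal), ("interaction", result.interactions)):
            if df.empty:
                continue
            df = df.copy()
            df.insert(0, "line", line_id)
            df.insert(1, "scan", kind)
            scan_tables.append(df)
        skipped.extend((line_id, locus, reason) for locus, reason in result.skipped)
        for locus in loci:
            g = grp[locus].to_numpy(dtype=float)
            for label, mask in (("carrier", g == 1), ("non_carrier", g == 0)):
                if mask.sum() == 0:
                    continue
                from .association import km_median

                med = km_median(
                    grp.loc[mask, "survival_days"], grp.loc[mask, "event"]
                )
                km_rows.append(
                    {"line": line_id, "locus": locus, "group": label,
                     "n": int(mask.sum()), "km_median_days": med}
                )
    for line_id, locus, reason in skipped:
        _log("associate", f"line {line_id}: skipped locus {locus}: {reason}")

    out.mkdir(parents=True, exist_ok=True)
    animals_out = animals.copy()
    animals_path = out / "animals.tsv"
    animals_out.to_csv(animals_path, sep="\t", index=False, na_rep="NA")
    segregation.to_csv(out / "segregation.tsv", sep="\t", index=False)
    if scan_tables:
        pd.concat(scan_tables, ignore_index=True).to_csv(
            out / "association.tsv", sep="\t", index=False, na_rep="NA"
        )
    report = {
        "seed": config.seed,
        "screen": config.screen,
        "n_animals": int(len(animals)),
        "n_lines": int(animals["line"].nunique()),
        "segregation": segregation.to_dict(orient="records"),
        "km_medians": km_rows,
        "skipped_loci": [
            {"line": l, "locus": loc, "reason": r} for l, loc, r in skipped
        ],
    }
    if spectrum is not None:
        report["spectrum"] = {
            "total": spectrum.total,
            "consequence_counts": spectrum.consequence_counts,
            "consequence_percent": spectrum.consequence_percent,
            "substitution_counts": spectrum.substitution_counts,
            "allele_tally": {str(k): v for k, v in spectrum.allele_tally.items()},
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "tool": "enuscreen",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": _config_snapshot(config),
        "input_checksums": {
            name: _sha256(path)
            for name, path in (
                ("phenotypes", config.phenotypes),
                ("genotypes", config.genotypes),
                ("survival", config.survival),
                ("variants", config.variants),
            )
            if path
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log("done", f"reports written to {out}")
    return out
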