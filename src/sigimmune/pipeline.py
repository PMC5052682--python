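"""Pipeline orchestration: simulate -> attribute -> annotate -> score -> associate.

A run is driven by a YAML config (all keys optional; an empty config runs a
fully synthetic cohort at the default study conditions), writes every stage
table as TSV under the output directory, and records a manifest with the
config hash, seed and a checksum of every written file.  A rerun against an
unchanged manifest skips stages whose outputs are intact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aa_properties, consequence, expression as expr_mod
from . import signatures as sig_mod
from . import stats as stats_mod
from . import synthetic

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    # synthetic mode (default): overrides for SyntheticCohortConfig
    simulate: dict | None = field(default_factory=dict)
    # real-input mode: file paths
    mutations: str | None = None
    fasta: str | None = None
    catalog: str | None = None
    expression: str | None = None
    clinical: str | None = None
    til_genes: str | None = None
    mcc_genes: str | None = None
    predictor: str = "hash"  # "hash", "constant", or a TSV path
    # thresholds
    hi: float = 0.50
    lo: float = 0.20
    min_n: int = 15
    ec50_threshold_nM: float = 50.0
    max_missing_frac: float = 0.20
    top_n: int = 5000
    exclude_signatures: list = field(default_factory=list)
    seed: int = 0

    def content_hash(self) -> str:
        blob = json.dumps(
            {f.name: getattr(self, f.name) for f in dc_fields(self)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config, reporting all problems at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    problems = [f"unknown key {k!r}" for k in raw if k not in known]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    for name, typ in (("hi", float), ("lo", float), ("ec50_threshold_nM", float),
                      ("max_missing_frac", float)):
        v = getattr(cfg, name)
        if not isinstance(v, (int, float)):
            problems.append(f"{name} must be a number, got {type(v).__name__}")
        else:
            setattr(cfg, name, typ(v))
    for name in ("min_n", "top_n", "seed"):
        if not isinstance(getattr(cfg, name), int):
            problems.append(f"{name} must be an integer")
    if isinstance(cfg.hi, float) and isinstance(cfg.lo, float):
        if not 0 <= cfg.lo < cfg.hi <= 1:
            problems.append(f"need 0 <= lo < hi <= 1, got lo={cfg.lo}, hi={cfg.hi}")
    if isinstance(cfg.ec50_threshold_nM, float) and cfg.ec50_threshold_nM <= 0:
        problems.append("ec50_threshold_nM must be positive")
    if isinstance(cfg.max_missing_frac, float) and not 0 <= cfg.max_missing_frac <= 1:
        problems.append("max_missing_frac must be in [0, 1]")
    if not isinstance(cfg.exclude_signatures, list):
        problems.append("exclude_signatures must be a list")
    if cfg.simulate is not None and not isinstance(cfg.simulate, dict):
        problems.append("simulate must be a mapping of generator overrides")
    if cfg.simulate is None:
        for name in ("mutations", "fasta", "catalog"):
            p = getattr(cfg, name)
            if p is None:
                problems.append(f"{name} path required when simulate is disabled")
            elif not Path(p).exists():
                problems.append(f"{name} file not found: {p}")
    for name in ("expression", "clinical", "til_genes", "mcc_genes"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name} file not found: {p}")
    if cfg.predictor not in ("hash", "constant") and not Path(cfg.predictor).exists():
        problems.append(f"predictor must be 'hash', 'constant' or a TSV path: {cfg.predictor}")
    if problems:
        raise ConfigError("; ".join(problems))
    return cfg


@dataclass
class ReportBundle:
    """Paths of every written table plus the run manifest."""

    out_dir: Path
    outputs: dict[str, Path]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _make_predictor(cfg: RunConfig):
    if cfg.predictor == "hash":
        return consequence.HashPredictor()
    if cfg.predictor == "constant":
        return consequence.ConstantPredictor()
    return consequence.TablePredictor.from_tsv(cfg.predictor)


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> ReportBundle:
    """Execute every applicable stage; stage failure aborts with partial
    outputs preserved."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    outputs: dict[str, Path] = {}
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
    resumable = (
        previous.get("config_hash") == config.content_hash()
        and previous.get("seed") == seed
    )
    if resumable:
        prior = {
            rel: out / rel for rel in previous.get("checksums", {})
        }
        intact = all(
            p.exists() and _sha256(p) == previous["checksums"][rel]
            for rel, p in prior.items()
        )
        if intact and prior:
            logger.info("outputs unchanged for this config+seed; skipping rerun")
            return ReportBundle(out, prior, previous)

    def save(name: str, frame: pd.DataFrame, index: bool = True) -> Path:
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=index, na_rep="NA")
        outputs[name] = p
        return p

    # ---- stage: inputs (simulate or load) -------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = synthetic.SyntheticCohortConfig(
                **{**config.simulate, "seed": seed}
            )
            in_dir = out / "inputs"
            cohort = synthetic.simulate_cohort(sim_cfg)
            paths = synthetic.write_cohort(cohort, in_dir)
            outputs.update({f"input_{k}": v for k, v in paths.items()})
            cds = cohort.cds
            catalog = cohort.catalog
            mutations = cohort.mutations
            expr = cohort.expression
            clinical = cohort.clinical
            til_list = cohort.modules["TIL"]
            mcc_list = cohort.modules["MCC"]
        else:
            cds = synthetic.read_fasta(config.fasta)
            catalog = synthetic.read_catalog_tsv(config.catalog)
            mutations = pd.read_csv(config.mutations, sep="\t")
            expr = (
                expr_mod.load_expression_tsv(config.expression)
                if config.expression else None
            )
            clinical = (
                pd.read_csv(config.clinical, sep="\t", index_col="sample_id")
                if config.clinical else None
            )
            til_list = (
                Path(config.til_genes).read_text().split()
                if config.til_genes else None
            )
            mcc_list = (
                Path(config.mcc_genes).read_text().split()
                if config.mcc_genes else None
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # ---- stage: attribute ----------------------------------------------
    try:
        classified = sig_mod.classify_mutations(mutations, cds)
        spectra = sig_mod.build_spectrum(classified, per_sample=True)
        exposures = sig_mod.fit_exposures_per_sample(spectra, catalog)
        attributions = sig_mod.attribute_mutations(
            classified, catalog, exposures[list(catalog.columns)]
        )
        counts, props = sig_mod.signature_proportions(
            attributions, signature_ids=list(catalog.columns)
        )
        save("exposures", exposures)
        save("attributions", attributions, index=False)
        save("signature_counts", counts)
        save("signature_proportions", props)
    except Exception as exc:
        raise StageError("attribute", exc) from exc

    # ---- stage: annotate ------------------------------------------------
    try:
        predictor = _make_predictor(config)
        annotations = consequence.annotate_cohort(
            attributions, cds, predictor,
            threshold_nM=config.ec50_threshold_nM,
        )
        save("annotations", annotations, index=False)
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # ---- stage: properties ---------------------------------------------
    try:
        by_sig = aa_properties.count_property_changes(annotations)
        per_sample = aa_properties.count_property_changes(annotations, per_sample=True)
        save("property_counts_by_signature", by_sig)
        save("property_counts_per_sample", per_sample)
        neo_frac = consequence.neoepitope_fraction_by_signature(annotations)
        save("neoepitope_fractions", neo_frac.to_frame())
    except Exception as exc:
        raise StageError("properties", exc) from exc

    # ---- stage: score (expression) --------------------------------------
    scores = None
    if expr is not None and til_list and mcc_list:
        try:
            til = expr_mod.geneset_score(expr, til_list, "TIL")
            mcc = expr_mod.geneset_score(expr, mcc_list, "MCC")
            til_group = expr_mod.quartile_group(til.scores)
            groups3 = expr_mod.til_mcc_groups(til.scores, mcc.scores)
            scores = pd.DataFrame({
                "til_score": til.scores, "mcc_score": mcc.scores,
                "til_group": til_group,
                "mcc_group": expr_mod.quartile_group(mcc.scores),
                "til_mcc_group": groups3.astype(str),
            }).rename_axis("sample_id")
            save("scores", scores)
        except Exception as exc:
            raise StageError("score", exc) from exc
    else:
        logger.info("no expression input: expression stages skipped")

    # ---- stage: associate -----------------------------------------------
    try:
        charge_counts = aa_properties.per_sample_charge_increase(
            annotations, samples=list(counts.index)
        ).reindex(columns=list(catalog.columns), fill_value=0)
        excl = tuple(str(s) for s in config.exclude_signatures)
        if scores is not None:
            common = counts.index.intersection(scores.index)
            til_assoc = stats_mod.per_signature_group_association(
                counts.loc[common], scores.loc[common, "til_group"],
                exclude_signatures=excl,
                group_order=["TOP_QUARTILE", "REST"],
            )
            save("til_association", til_assoc)
        if clinical is not None:
            common = counts.index.intersection(clinical.index)
            infl = clinical.loc[common, "infiltrate"]
            trend_tab = stats_mod.infiltrate_trend_per_signature(
                counts.loc[common], infl, exclude_signatures=excl
            )
            save("infiltrate_trend", trend_tab)
            charge_rows = []
            cc = charge_counts.loc[common]
            specs = [("ALL", ())] + [(s, ()) for s in catalog.columns] + [
                ("ALL", (s,)) for s in catalog.columns
            ]
            for sig_id, exclude in specs:
                try:
                    res = aa_properties.charge_increase_trend(
                        cc, infl, signature_id=sig_id, exclude=exclude
                    )
                    charge_rows.append({
                        "signature": sig_id,
                        "excluded": ",".join(exclude) or "-",
                        "z": res.z, "p": res.p, "note": res.note,
                    })
                except (ValueError, KeyError) as exc:
                    charge_rows.append({
                        "signature": sig_id, "excluded": ",".join(exclude) or "-",
                        "z": np.nan, "p": np.nan, "note": str(exc),
                    })
            save("charge_increase_trend", pd.DataFrame(charge_rows), index=False)
        if clinical is not None and scores is not None:
            common = scores.index.intersection(clinical.index)
            surv = pd.DataFrame({
                "time": clinical.loc[common, "time_months"],
                "event": clinical.loc[common, "event"],
                "group": scores.loc[common, "til_mcc_group"],
            })
            res, km = stats_mod.km_logrank(
                surv, trend=True, group_order=expr_mod.TIL_MCC_LEVELS
            )
            surv_rows = [{
                "test": res.test, "statistic": res.statistic, "z": res.z,
                "p": res.p, **{f"n_{k}": v for k, v in res.group_ns.items()},
            }]
            cox = stats_mod.cox_ph(
                scores.loc[common, ["til_score", "mcc_score"]],
                surv,
            )
            save("cox_model", cox)
            save("survival_tests", pd.DataFrame(surv_rows), index=False)
            for lev, tab in km.items():
                save(f"km_{str(lev)}", tab, index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("associate", exc) from exc

    manifest = {
        "package": "sigimmune",
        "version": __version__,
        "seed": seed,
        "config_hash": config.content_hash(),
        "resumed": bool(resumable),
        "checksums": {
            str(p.relative_to(out)): _sha256(p) for p in outputs.values()
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(out, outputs, manifest)
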