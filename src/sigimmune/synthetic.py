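"""Synthetic cohort generator.

Generates every input the analysis pipeline consumes — coding sequences, a
toy 96-class signature catalog, per-sample mutation tables drawn from
signature mixtures placed on those sequences, a log2 expression matrix with
planted TIL / mitotic-cell-cycle (MCC) gene modules, and a clinical table
with proportional-hazards survival times and an ordinal lymphocytic-
infiltrate label — with the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any external data.

Every simulated mutation carries its generating signature as ground truth
(``true_signature``) for attribution-accuracy tests.  A single integer seed
drives all stages through fixed named sub-streams, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aa_properties, consequence
from .signatures import CONTEXT_CLASSES, trinucleotide_context, validate_catalog

logger = logging.getLogger(__name__)

_STOP_CODONS = ("TAA", "TAG", "TGA")
_STREAMS = {"cds": 0, "exposures": 1, "mutations": 2, "expression": 3, "clinical": 4}

TOY_SIGNATURE_IDS = ("age_like", "apobec_CtoT", "apobec_CtoG", "flat", "brca_like")


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Stage-local RNG derived from the global seed by a fixed named offset."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the target cohort scale: 266 samples, a Poisson mean of
    100 coding substitutions per sample, symmetric-Dirichlet(1) exposure
    mixtures over four toy signatures, and planted effects linking the MCC
    module to total burden, the TIL module to APOBEC-C>G-attributed counts,
    the ordinal infiltrate to charge-increasing APOBEC-C>G counts, and the
    hazard to the MCC (up) and TIL (down) scores.
    """

    n_samples: int = 266
    n_genes: int = 30
    cds_length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.45
    signature_ids: tuple[str, ...] = ("age_like", "apobec_CtoT", "apobec_CtoG", "flat")
    exposure_concentration: float = 1.0
    mutations_per_sample_mean: float = 100.0
    effect_sizes: dict = field(default_factory=lambda: {
        "mcc_vs_total_burden": 0.8,
        "til_vs_apobec": 0.8,
        "infiltrate_vs_charge_increase": 1.0,
        "hazard_mcc": 0.7,
        "hazard_til": -0.7,
    })
    censor_rate: float = 0.3
    seed: int = 0
    # secondary knobs
    charge_signature: str = "apobec_CtoG"
    module_size: int = 20
    n_background_genes: int = 200
    expression_noise_sd: float = 0.5
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("n_samples", "n_genes", "module_size", "n_background_genes"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        lo, hi = self.cds_length_range
        if lo < 30 or hi < lo:
            problems.append("cds_length_range must be (lo, hi) with lo >= 30")
        for name in ("gc_content",):
            v = getattr(self, name)
            if not 0 < v < 1:
                problems.append(f"{name} must be in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            problems.append("censor_rate must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            problems.append("missing_rate must be in [0, 1)")
        if self.exposure_concentration <= 0:
            problems.append("exposure_concentration must be positive")
        if self.mutations_per_sample_mean <= 0:
            problems.append("mutations_per_sample_mean must be positive")
        unknown = set(self.signature_ids) - set(TOY_SIGNATURE_IDS)
        if unknown:
            problems.append(
                f"unknown signature ids {sorted(unknown)}; supported: {TOY_SIGNATURE_IDS}"
            )
        if self.charge_signature not in self.signature_ids:
            problems.append("charge_signature must be one of signature_ids")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


# ------------------------------------------------------------ reference CDS

def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3, p=p))
        if codon not in _STOP_CODONS:
            return codon


def generate_reference_cds(
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> dict[str, str]:
    """Generate ``n_genes`` coding sequences.

    Each CDS starts with ATG, has no internal stop codon, ends with a stop
    codon, and its coding body's GC content lies within 0.05 of the target
    (enforced by rejection; an unreachable target is an explicit error).
    """
    if rng is None:
        rng = stream_rng(config.seed, "cds")
    lo, hi = config.cds_length_range
    out: dict[str, str] = {}
    for g in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        length -= length % 3
        n_body = length // 3 - 2  # minus start and stop codons
        for _ in range(max_tries):
            body = "".join(_random_codon(rng, config.gc_content) for _ in range(n_body))
            gc = (body.count("G") + body.count("C")) / max(len(body), 1)
            if abs(gc - config.gc_content) <= 0.05:
                break
        else:
            raise ValueError(
                f"could not reach GC target {config.gc_content} within +/-0.05 "
                f"for a body of {n_body} codons"
            )
        stop = _STOP_CODONS[int(rng.integers(3))]
        out[f"gene_{g + 1:04d}"] = "ATG" + body + stop
    return out


# ------------------------------------------------------------- toy catalog

def _profile(mass_classes: list[str], concentration: float = 0.95) -> np.ndarray:
    probs = np.full(96, (1 - concentration) / (96 - len(mass_classes)))
    for c in mass_classes:
        probs[CONTEXT_CLASSES.index(c)] = concentration / len(mass_classes)
    return probs


def make_toy_catalog(signature_ids) -> pd.DataFrame:
    """Toy 96 x S catalog over the supported signature set.

    ``age_like`` concentrates on C>T at NCG, the two ``apobec_*`` profiles on
    C>T / C>G at TCN (>=90% of mass on their motif classes), ``flat`` is
    uniform over all 96 classes and ``brca_like`` is broadly patterned
    (uniform over all C-reference classes).
    """
    unknown = [s for s in signature_ids if s not in TOY_SIGNATURE_IDS]
    if unknown:
        raise ValueError(
            f"unknown signature id(s) {unknown}; supported: {list(TOY_SIGNATURE_IDS)}"
        )
    cols = {}
    for sig in signature_ids:
        if sig == "flat":
            probs = np.full(96, 1.0 / 96)
        elif sig == "apobec_CtoT":
            probs = _profile([f"T[C>T]{b}" for b in "ACGT"])
        elif sig == "apobec_CtoG":
            probs = _profile([f"T[C>G]{b}" for b in "ACGT"])
        elif sig == "age_like":
            probs = _profile([f"{b}[C>T]G" for b in "ACGT"])
        else:  # brca_like
            c_classes = [c for c in CONTEXT_CLASSES if "[C>" in c]
            probs = np.zeros(96)
            for c in c_classes:
                probs[CONTEXT_CLASSES.index(c)] = 1.0 / len(c_classes)
        cols[sig] = probs
    catalog = pd.DataFrame(cols, index=CONTEXT_CLASSES)
    validate_catalog(catalog)
    return catalog


# --------------------------------------------------------------- mutations

def build_site_index(cds: dict[str, str]) -> dict[str, list[tuple[str, int, str, str]]]:
    """Map each 96-class to every (gene, pos, ref, alt) realizing it."""
    sites: dict[str, list[tuple[str, int, str, str]]] = {c: [] for c in CONTEXT_CLASSES}
    for gene, seq in cds.items():
        for pos in range(2, len(seq)):
            ref = seq[pos - 1]
            if ref not in "ACGT":
                continue
            for alt in "ACGT":
                if alt == ref:
                    continue
                label = trinucleotide_context(seq, pos, ref, alt)
                sites[label].append((gene, pos, ref, alt))
    return sites


def simulate_mutations(
    cds: dict[str, str],
    catalog: pd.DataFrame,
    exposures: pd.DataFrame,
    n_per_sample,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> pd.DataFrame:
    """Draw per-sample mutation catalogs from signature mixtures.

    For each mutation a signature is drawn from the sample's exposures, a
    96-class from that signature's profile, and a concrete site uniformly
    from the reference sites realizing that class.  A sampled class with no
    site in the reference is redrawn up to ``max_retries`` times, then it is
    an error.  Output columns: sample_id, gene_id, pos_1based_cds, ref, alt,
    strand (always '+'), context, true_signature.
    """
    validate_catalog(catalog)
    if (exposures.values < 0).any():
        raise ValueError("negative exposures")
    if not np.allclose(exposures.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("exposure rows must sum to 1")
    sites = build_site_index(cds)
    sig_ids = list(catalog.columns)
    profiles = catalog.values  # 96 x S
    if np.isscalar(n_per_sample):
        n_per_sample = pd.Series(int(n_per_sample), index=exposures.index)

    pools = [sites[c] for c in CONTEXT_CLASSES]
    pool_sizes = np.array([len(p) for p in pools])
    records = []
    for sample in exposures.index:
        w = exposures.loc[sample].values.astype(float)
        n = int(n_per_sample.loc[sample])
        if n == 0:
            continue
        per_sig = rng.multinomial(n, w)
        for s, k in enumerate(per_sig):
            if k == 0:
                continue
            classes = rng.choice(96, size=k, p=profiles[:, s])
            bad = pool_sizes[classes] == 0
            tries = 0
            while bad.any():
                tries += 1
                if tries > max_retries:
                    missing = {CONTEXT_CLASSES[c] for c in classes[bad]}
                    raise RuntimeError(
                        f"classes with no reference site after {max_retries} "
                        f"retries: {sorted(missing)}"
                    )
                classes[bad] = rng.choice(96, size=int(bad.sum()), p=profiles[:, s])
                bad = pool_sizes[classes] == 0
            site_idx = rng.integers(0, pool_sizes[classes])
            for c, j in zip(classes, site_idx):
                gene, pos, ref, alt = pools[c][j]
                records.append(
                    (sample, gene, pos, ref, alt, "+", CONTEXT_CLASSES[c], sig_ids[s])
                )
    return pd.DataFrame(
        records,
        columns=["sample_id", "gene_id", "pos_1based_cds", "ref", "alt",
                 "strand", "context", "true_signature"],
    )


# -------------------------------------------------------------- expression

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_expression(
    samples: list[str],
    module_spec: dict[str, dict],
    covariates: pd.DataFrame,
    noise_sd: float,
    rng: np.random.Generator,
    n_background: int = 200,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Log2 expression matrix with planted co-expressed gene modules.

    ``module_spec`` maps a module name to ``{"genes": [...], "covariate":
    name, "effect": beta}``; each module gene's expression is its own
    baseline plus ``beta`` times the standardized covariate plus Gaussian
    noise, so the per-sample module mean correlates with the covariate with
    the sign of ``beta``.  Modules must be disjoint.  Background genes have
    heterogeneous variances and no planted structure.  Missing values (rate
    ``missing_rate``, at random) are NaN (written as "NA" in TSV).
    """
    all_module_genes: list[str] = []
    for name, spec in module_spec.items():
        overlap = set(spec["genes"]) & set(all_module_genes)
        if overlap:
            raise ValueError(f"modules overlap on genes {sorted(overlap)}")
        all_module_genes.extend(spec["genes"])
        if spec["covariate"] not in covariates.columns:
            raise KeyError(f"module {name}: covariate {spec['covariate']!r} unknown")
    n = len(samples)
    rows = {}
    for name, spec in module_spec.items():
        z = _standardize(covariates.loc[samples, spec["covariate"]].values.astype(float))
        for g in spec["genes"]:
            base = rng.normal(5.0, 1.0)
            noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
            rows[g] = base + spec["effect"] * z + noise
    for b in range(n_background):
        base = rng.normal(5.0, 1.5)
        sd = rng.uniform(0.2, 2.0)
        rows[f"bg_{b + 1:04d}"] = base + rng.normal(0.0, sd, n)
    mat = pd.DataFrame(rows, index=samples).T
    mat.index.name = "transcript_id"
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat = mat.mask(mask)
    return mat


# ---------------------------------------------------------------- clinical

def _censoring_horizon(event_times: np.ndarray, rate: float) -> float:
    """Solve for tau so uniform(0, tau) censoring removes ~``rate`` of events."""
    def censored_frac(tau: float) -> float:
        return float(np.mean(np.minimum(event_times / tau, 1.0)))

    lo, hi = 1e-9, float(event_times.max()) * 2
    while censored_frac(hi) > rate:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if censored_frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_clinical(
    scores: pd.DataFrame,
    hazard_betas: dict[str, float],
    infiltrate_betas: dict[str, float],
    censor_rate: float,
    rng: np.random.Generator,
    baseline_hazard_per_month: float = 0.02,
) -> pd.DataFrame:
    """Survival times and ordinal infiltrate driven by per-sample scores.

    Event times are exponential with hazard proportional to
    ``exp(sum beta_k * z(score_k))``; censoring is independent uniform on
    ``(0, tau)`` with tau solved so the expected censored fraction equals
    ``censor_rate``.  The infiltrate label is a latent Gaussian with mean
    ``sum gamma_k * z(score_k)`` cut at its empirical tertiles into three
    ordered levels 0 < 1 < 2 (none < mild < moderate-severe).
    """
    if not np.isfinite(scores.values.astype(float)).all():
        raise ValueError("non-finite values in scores")
    for key in list(hazard_betas) + list(infiltrate_betas):
        if key not in scores.columns:
            raise KeyError(f"score column {key!r} missing")
    n = len(scores)
    eta = np.zeros(n)
    for key, beta in hazard_betas.items():
        eta += beta * _standardize(scores[key].values.astype(float))
    lam = baseline_hazard_per_month * np.exp(eta)
    event_times = rng.exponential(1.0 / lam)
    if censor_rate == 0:
        time, event = event_times, np.ones(n, dtype=int)
    else:
        tau = _censoring_horizon(event_times, censor_rate)
        censor_times = rng.uniform(0.0, tau, n)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)

    latent = rng.normal(0.0, 1.0, n)
    for key, gamma in infiltrate_betas.items():
        latent += gamma * _standardize(scores[key].values.astype(float))
    cuts = np.quantile(latent, [1 / 3, 2 / 3])
    infiltrate = np.digitize(latent, cuts)

    return pd.DataFrame(
        {
            "time_months": time,
            "event": event,
            "infiltrate": infiltrate,
            "grade": rng.integers(1, 4, n),
            "er_status": rng.choice(["positive", "negative"], size=n, p=[0.72, 0.28]),
        },
        index=scores.index,
    ).rename_axis("sample_id")


# ------------------------------------------------------------ whole cohort

@dataclass
class SimulatedCohort:
    """All generated inputs plus the hidden ground truth."""

    config: SyntheticCohortConfig
    cds: dict[str, str]
    catalog: pd.DataFrame
    true_exposures: pd.DataFrame
    mutations: pd.DataFrame
    covariates: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame
    modules: dict[str, list[str]]


def simulate_cohort(config: SyntheticCohortConfig) -> SimulatedCohort:
    """Generate a complete cohort under the configured study conditions."""
    cds = generate_reference_cds(config)
    catalog = make_toy_catalog(config.signature_ids)

    rng_e = stream_rng(config.seed, "exposures")
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    expo = pd.DataFrame(
        rng_e.dirichlet(
            np.full(len(config.signature_ids), config.exposure_concentration),
            size=config.n_samples,
        ),
        index=samples, columns=list(config.signature_ids),
    )
    n_per_sample = pd.Series(
        rng_e.poisson(config.mutations_per_sample_mean, config.n_samples),
        index=samples,
    )
    rng_m = stream_rng(config.seed, "mutations")
    mutations = simulate_mutations(cds, catalog, expo, n_per_sample, rng_m)

    # mutation-derived covariates from the ground-truth labels
    true_counts = (
        mutations.groupby("sample_id")["true_signature"].value_counts()
        .unstack(fill_value=0)
        .reindex(index=samples, columns=list(config.signature_ids), fill_value=0)
    )
    annotated = consequence.annotate_mutations(mutations, cds)
    charge_inc = aa_properties.per_sample_charge_increase(
        annotated, attribution_col="true_signature", samples=samples
    ).reindex(columns=list(config.signature_ids), fill_value=0)
    covariates = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    covariates["total_mutations"] = true_counts.sum(axis=1)
    for sig in config.signature_ids:
        covariates[f"count_{sig}"] = true_counts[sig]
        covariates[f"charge_increase_{sig}"] = charge_inc[sig]

    eff = config.effect_sizes
    modules = {
        "MCC": [f"MCC_{i + 1:03d}" for i in range(config.module_size)],
        "TIL": [f"TIL_{i + 1:03d}" for i in range(config.module_size)],
    }
    module_spec = {
        "MCC": {"genes": modules["MCC"], "covariate": "total_mutations",
                "effect": eff.get("mcc_vs_total_burden", 0.0)},
        "TIL": {"genes": modules["TIL"],
                "covariate": f"count_{config.charge_signature}",
                "effect": eff.get("til_vs_apobec", 0.0)},
    }
    rng_x = stream_rng(config.seed, "expression")
    expression = simulate_expression(
        samples, module_spec, covariates, config.expression_noise_sd, rng_x,
        n_background=config.n_background_genes, missing_rate=config.missing_rate,
    )
    covariates["mcc_score"] = expression.loc[modules["MCC"]].mean(axis=0)
    covariates["til_score"] = expression.loc[modules["TIL"]].mean(axis=0)

    rng_c = stream_rng(config.seed, "clinical")
    clinical = simulate_clinical(
        covariates,
        hazard_betas={"mcc_score": eff.get("hazard_mcc", 0.0),
                      "til_score": eff.get("hazard_til", 0.0)},
        infiltrate_betas={
            f"charge_increase_{config.charge_signature}":
                eff.get("infiltrate_vs_charge_increase", 0.0)
        },
        censor_rate=config.censor_rate,
        rng=rng_c,
    )
    return SimulatedCohort(
        config, cds, catalog, expo, mutations, covariates, expression,
        clinical, modules,
    )


# ---------------------------------------------------------------- file I/O

def write_fasta(cds: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=g, description="") for g, s in cds.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}


def write_catalog_tsv(catalog: pd.DataFrame, path) -> None:
    catalog.rename_axis("context").to_csv(path, sep="\t")


def read_catalog_tsv(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t", index_col=0)
    validate_catalog(cat)
    return cat


def write_mutations_tsv(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t")


def write_vcf(mutations: pd.DataFrame, path) -> None:
    """Minimal VCF export: CHROM = gene id, POS = 1-based CDS position."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in mutations.itertuples(index=False):
            fh.write(
                f"{row.gene_id}\t{row.pos_1based_cds}\t.\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\tSAMPLE={row.sample_id}\n"
            )


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write every cohort table under ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference_cds.fa",
        "catalog": out / "catalog.tsv",
        "mutations": out / "mutations.tsv",
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "exposures_true": out / "true_exposures.tsv",
        "til_genes": out / "til_genes.tsv",
        "mcc_genes": out / "mcc_genes.tsv",
    }
    write_fasta(cohort.cds, paths["fasta"])
    write_catalog_tsv(cohort.catalog, paths["catalog"])
    write_mutations_tsv(cohort.mutations, paths["mutations"])
    write_expression_tsv(cohort.expression, paths["expression"])
    write_clinical_tsv(cohort.clinical, paths["clinical"])
    cohort.true_exposures.rename_axis("sample_id").to_csv(
        paths["exposures_true"], sep="\t"
    )
    for name, key in (("TIL", "til_genes"), ("MCC", "mcc_genes")):
        Path(paths[key]).write_text("\n".join(cohort.modules[name]) + "\n")
    return paths
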