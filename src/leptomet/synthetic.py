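"""Synthetic paired-intervention metabolome studies with planted truth.

The generator emulates the shape of a small paired leptin-replacement study:
6 individuals sampled pre and post treatment, 661 metabolites split across
the platform's 7 super-pathways (368 lipids, 170 amino acids, 35
nucleotides, 34 peptides, 23 cofactors and vitamins, 21 carbohydrates, 10
TCA-cycle intermediates), with named lipid sub-pathways (fatty acids by
chain-length class, acylcarnitines, bile acids) so the lipid-structure tests
have something to chew on.

Generative model, on the log10 scale:

    x[i, g, cond] = mu_g + b[i, g] + covariate effects + noise
                  + delta * 1[g in shifted sub-pathway, cond = post]
                  + loading * sign_g * f_i * 1[g in module, cond = post]

with per-metabolite baselines mu_g ~ N(6, 1), individual offsets
b ~ N(0, individual_sd) shared between an individual's two samples (the
strong inter-individual variation such cohorts show), and iid noise.  BMI is
generated at the individual level from the signature metabolites' offsets,
so score recovery has a known planted correlation.  Missingness is
left-censoring: values below a per-metabolite quantile are unrecorded,
matching detection limits and justifying minimum-based imputation.  Exported
tables are on the raw scale (10^x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import AbundanceMatrix

SUPERPATHWAY_COUNTS = {
    "Lipid": 368,
    "Amino Acid": 170,
    "Nucleotide": 35,
    "Peptide": 34,
    "Cofactors and Vitamins": 23,
    "Carbohydrate": 21,
    "Energy": 10,
}

#: Named lipid sub-pathways (size, kind); the rest of each super-pathway is
#: chunked into generic sub-pathways of ~8 metabolites.
NAMED_LIPID_SUBPATHWAYS = (
    ("medium chain fatty acid", 7, "fa_medium"),
    ("long chain fatty acid", 14, "fa_long"),
    ("polyunsaturated fatty acid (n3 and n6)", 12, "fa_pufa"),
    ("fatty acid metabolism (acyl carnitine)", 30, "acylcarnitine"),
    ("primary bile acid metabolism", 12, "bile_primary"),
    ("secondary bile acid metabolism", 13, "bile_secondary"),
    ("sphingolipid metabolism", 12, "generic"),
    ("phosphatidylcholine (pc)", 12, "generic"),
    ("lysophospholipid", 12, "generic"),
)

GENERIC_CHUNK = 8


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the emulated study."""

    n_individuals: int = 6
    n_metabolites: int = 661
    superpathway_counts: dict = field(default_factory=lambda: dict(SUPERPATHWAY_COUNTS))
    # planted class-wide shift (log10 units) applied post-treatment
    shifted_subpathway: str = "long chain fatty acid"
    delta: float = 0.3
    # planted post-only correlation module
    module_size: int = 15
    module_loading: float = 0.9
    module_n_positive: int = 8
    # planted BMI signature
    n_signature: int = 49
    bmi_effect: float = 10.0
    bmi_base: float = 40.0
    bmi_noise_sd: float = 4.0
    # variance components (log10 units)
    noise_sd: float = 0.15
    individual_sd: float = 0.3
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    # nuisance covariate effect scales (SD of per-metabolite coefficients)
    sex_effect_sd: float = 0.1
    age_effect_sd: float = 0.01
    run_day_effect_sd: float = 0.1
    n_run_days: int = 3
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.superpathway_counts.values()) != self.n_metabolites:
            raise ValueError("super-pathway counts must sum to n_metabolites")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if not 0 <= self.module_loading <= 1:
            raise ValueError("module loading must lie in [0, 1]")
        if self.module_size > self.n_metabolites:
            raise ValueError("module larger than the metabolome")

    @classmethod
    def scaled_down(cls, n_metabolites: int, **kwargs) -> "SimulationConfig":
        """Config with the super-pathway mix rescaled to a smaller metabolome."""
        base = SUPERPATHWAY_COUNTS
        counts = {k: max(3, round(v * n_metabolites / 661)) for k, v in base.items()}
        counts["Lipid"] += n_metabolites - sum(counts.values())
        return cls(n_metabolites=n_metabolites, superpathway_counts=counts, **kwargs)


@dataclass
class GroundTruth:
    """Planted effects, emitted alongside the study tables."""

    shifted_metabolites: dict  # metabolite_id -> true log10 effect
    module_members: dict  # metabolite_id -> submodule sign
    signature: dict  # metabolite_id -> direction
    bmi: pd.Series  # individual_id -> BMI
    composite: pd.Series  # individual_id -> planted score composite
    r_planted: float = np.nan  # population corr(composite, BMI) implied by config
    #: population corr(score, BMI) for a fully matched score: r_planted times
    #: the measurement-noise attenuation individual_sd / sqrt(ind^2 + noise^2)
    r_planted_score: float = np.nan


def _build_annotation(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    gid = 0

    def next_id():
        nonlocal gid
        gid += 1
        return f"M{gid:04d}"

    for sp, count in config.superpathway_counts.items():
        remaining = count
        if sp == "Lipid":
            # scale the named sub-pathways with the lipid panel size so
            # scaled-down studies keep the same composition
            scale = count / SUPERPATHWAY_COUNTS["Lipid"]
            named = [
                (sub_name, max(3, round(size * scale)), kind)
                for sub_name, size, kind in NAMED_LIPID_SUBPATHWAYS
            ]
            while sum(s for _, s, _ in named) > count:
                j = max(range(len(named)), key=lambda i: named[i][1])
                if named[j][1] <= 3:
                    named = named[:-1]
                    continue
                named[j] = (named[j][0], named[j][1] - 1, named[j][2])
            for sub_name, size, kind in named:
                for k in range(size):
                    row = {
                        "metabolite_id": next_id(),
                        "super_pathway": sp,
                        "sub_pathway": sub_name,
                    }
                    if kind == "fa_medium":
                        c, d = 6 + k % 7, int(rng.integers(0, 2))
                    elif kind == "fa_long":
                        c, d = 13 + k % 9, int(rng.integers(0, 2))
                    elif kind == "fa_pufa":
                        c, d = 18 + k % 5, int(rng.integers(2, 5))
                    elif kind == "acylcarnitine":
                        c, d = 2 + 2 * (k % 10), int(rng.integers(0, 3))
                    else:
                        c = d = None
                    if kind.startswith("fa_"):
                        row["biochemical_name"] = f"nefa ({c}:{d})"
                        row["chain_length"], row["double_bonds"] = c, d
                    elif kind == "acylcarnitine":
                        row["biochemical_name"] = f"acylcarnitine ({c}:{d})"
                        row["chain_length"], row["double_bonds"] = c, d
                    elif kind.startswith("bile"):
                        which = "primary" if kind == "bile_primary" else "secondary"
                        row["biochemical_name"] = f"{which} bile acid {k + 1:02d}*"
                        row["is_12a_hydroxylated"] = bool(k % 2)
                    else:
                        row["biochemical_name"] = f"{sub_name} species {k + 1:02d}"
                    rows.append(row)
                remaining -= size
        chunk = 0
        while remaining > 0:
            size = min(GENERIC_CHUNK, remaining)
            if 0 < remaining - size < 3:  # avoid trailing micro-pathways
                size = remaining
            chunk += 1
            sub_name = f"{sp.lower()} class {chunk:02d}"
            for k in range(size):
                rows.append(
                    {
                        "metabolite_id": next_id(),
                        "super_pathway": sp,
                        "sub_pathway": sub_name,
                        "biochemical_name": f"{sub_name} metabolite {k + 1:02d}",
                    }
                )
            remaining -= size
    ann = pd.DataFrame(rows)
    for col in ("chain_length", "double_bonds", "is_12a_hydroxylated"):
        if col not in ann.columns:
            ann[col] = np.nan
    return ann


def simulate_study(config: SimulationConfig | None = None):
    """Generate one study: (AbundanceMatrix raw, annotations, metadata, truth)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    ann = _build_annotation(config, rng)
    ids = ann["metabolite_id"].to_numpy()
    m = len(ids)
    n = config.n_individuals

    # per-metabolite baselines drawn first so planted structures can be
    # placed on well-quantified (comfortably above detection limit)
    # metabolites, as any analysis of a delivered panel would see them
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=m)

    # planted structures ---------------------------------------------------
    shifted_ids = ann.loc[ann["sub_pathway"] == config.shifted_subpathway, "metabolite_id"]
    shifted = {mid: config.delta for mid in shifted_ids}

    abundant = set(ids[mu >= np.median(mu)])
    forbidden = set(shifted)
    candidates = [mid for mid in ids if mid not in forbidden and mid in abundant]
    module_ids = list(rng.choice(candidates, size=config.module_size, replace=False))
    module_signs = {
        mid: (1 if k < config.module_n_positive else -1) for k, mid in enumerate(module_ids)
    }

    forbidden |= set(module_ids)
    candidates = [mid for mid in ids if mid not in forbidden and mid in abundant]
    n_signature = min(config.n_signature, len(candidates))
    signature_ids = list(rng.choice(candidates, size=n_signature, replace=False))
    signature = {mid: (1 if k % 2 == 0 else -1) for k, mid in enumerate(signature_ids)}

    # individuals and covariates ------------------------------------------
    individuals = [f"I{k + 1:03d}" for k in range(n)]
    sex = np.array(["F" if k % 2 else "M" for k in range(n)])
    age = rng.uniform(2.0, 18.0, size=n)
    ethnicity = np.array([("Pakistani", "Turkish", "Arab")[k % 3] for k in range(n)])

    b = rng.normal(0.0, config.individual_sd, size=(n, m))
    beta_sex = rng.normal(0.0, config.sex_effect_sd, size=m)
    beta_age = rng.normal(0.0, config.age_effect_sd, size=m)
    beta_day = rng.normal(0.0, config.run_day_effect_sd, size=(config.n_run_days, m))

    col_index = {mid: k for k, mid in enumerate(ids)}
    delta_vec = np.zeros(m)
    for mid, eff in shifted.items():
        delta_vec[col_index[mid]] = eff
    module_cols = np.array([col_index[mid] for mid in module_ids])
    sign_vec = np.array([module_signs[mid] for mid in module_ids], dtype=float)
    factor = rng.normal(0.0, 1.0, size=n)

    sample_rows = []
    data_rows = []
    run_days = np.array([k % config.n_run_days for k in range(2 * n)])
    rng.shuffle(run_days)
    s = 0
    for i, iid in enumerate(individuals):
        for cond in ("pre", "post"):
            day = run_days[s]
            x = (
                mu
                + b[i]
                + beta_sex * (sex[i] == "F")
                + beta_age * (age[i] - 10.0)
                + beta_day[day]
                + rng.normal(0.0, config.noise_sd, size=m)
            )
            if cond == "post":
                x = x + delta_vec
                # Treatment reorganizes the module members' inter-individual
                # variation into a coordinated latent axis: the factor term
                # replaces the individual offset (so the within-module post
                # correlation is loading^2 / (loading^2 + noise_sd^2)).
                x[module_cols] += (
                    config.module_loading * sign_vec * factor[i] - b[i, module_cols]
                )
            data_rows.append(x)
            sample_rows.append(
                {
                    "sample_id": f"{iid}_{cond}",
                    "individual_id": iid,
                    "condition": cond,
                    "sex": sex[i],
                    "age": round(float(age[i]), 1),
                    "ethnicity": ethnicity[i],
                    "run_day": f"day{day + 1}",
                }
            )
            s += 1

    log_values = np.vstack(data_rows)

    # BMI from the signature metabolites' individual-level offsets ---------
    sig_cols = np.array([col_index[mid] for mid in signature_ids])
    dir_vec = np.array([signature[mid] for mid in signature_ids], dtype=float)
    composite = (b[:, sig_cols] * dir_vec).sum(axis=1) / np.sqrt(len(signature_ids))
    bmi = config.bmi_base + config.bmi_effect * composite + rng.normal(
        0.0, config.bmi_noise_sd, size=n
    )
    bmi_map = dict(zip(individuals, bmi))
    metadata = pd.DataFrame(sample_rows)
    metadata["bmi"] = metadata["individual_id"].map(bmi_map).round(2)

    # left-censoring and export on the raw scale ---------------------------
    raw = np.power(10.0, log_values)
    if config.missing_rate > 0:
        # Detection-limit censoring: one global intensity threshold chosen so
        # the overall missing fraction equals missing_rate.  Low-abundance
        # metabolites carry most of the missingness; abundant ones stay
        # complete, as in real panels.
        limit = np.quantile(raw, config.missing_rate)
        raw = np.where(raw < limit, np.nan, raw)
        refill = np.isnan(raw).all(axis=0)  # never censor a metabolite away entirely
        raw[:, refill] = np.power(10.0, log_values[:, refill])

    matrix = AbundanceMatrix(
        pd.DataFrame(raw, index=[r["sample_id"] for r in sample_rows], columns=ids),
        log_scale=False,
    )
    r_planted = (
        config.bmi_effect
        * config.individual_sd
        / np.hypot(config.bmi_effect * config.individual_sd, config.bmi_noise_sd)
        if config.bmi_effect
        else 0.0
    )
    truth = GroundTruth(
        shifted_metabolites=shifted,
        module_members=module_signs,
        signature=signature,
        bmi=pd.Series(bmi, index=individuals, name="bmi"),
        composite=pd.Series(composite, index=individuals, name="composite"),
        r_planted=r_planted,
        r_planted_score=r_planted
        * config.individual_sd
        / np.hypot(config.individual_sd, config.noise_sd),
    )
    return matrix, ann, metadata.set_index("sample_id", drop=False), truth


def write_study(outdir, matrix, annotations, metadata, truth) -> None:
    """Export the study as the three TSVs plus a truth JSON."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.data.rename_axis("sample_id").to_csv(out / "abundance.tsv", sep="\t")
    annotations.to_csv(out / "annotation.tsv", sep="\t", index=False)
    metadata.reset_index(drop=True).to_csv(out / "metadata.tsv", sep="\t", index=False)
    payload = {
        "shifted_metabolites": truth.shifted_metabolites,
        "module_members": truth.module_members,
        "signature": truth.signature,
        "bmi": truth.bmi.to_dict(),
        "composite": truth.composite.to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))


def simulate_other_study(
    truth: GroundTruth,
    annotations: pd.DataFrame,
    fc_noise_sd: float = 0.1,
    overlap: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """A second study's fold-change table for concordance testing.

    Shares a random fraction ``overlap`` of metabolites (names decorated with
    an asterisk to exercise normalized matching); shared fold changes are the
    first study's true effects plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    keep = rng.random(len(annotations)) < overlap
    sub = annotations[keep]
    fc = np.array(
        [truth.shifted_metabolites.get(mid, 0.0) for mid in sub["metabolite_id"]]
    ) + rng.normal(0.0, fc_noise_sd, size=keep.sum())
    return pd.DataFrame(
        {
            "metabolite_id": [f"B{k + 1:04d}" for k in range(keep.sum())],
            "biochemical_name": [str(x) + "*" for x in sub["biochemical_name"]],
            "sub_pathway": sub["sub_pathway"].to_numpy(),
            "log10_fold_change": fc,
            "significant_flag": np.abs(fc) > 2 * fc_noise_sd,
        }
    )


def recovery_report(results: dict, truth: GroundTruth) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth.

    ``results`` may contain keys ``differential`` (frame), ``enrichment``
    (frame), ``modules`` (list of Module), ``scores`` (per-sample series)
    with ``metadata``; only supplied stages are scored.
    """
    out: dict = {}
    shifted = set(truth.shifted_metabolites)

    if "differential" in results:
        diff = results["differential"]
        if shifted - set(diff["metabolite_id"]):
            raise ValueError("differential results do not cover the planted metabolites")
        called_nominal = set(diff.loc[diff["p_raw"] < 0.05, "metabolite_id"])
        called_fdr = set(diff.loc[diff["p_adj"] < 0.2, "metabolite_id"])
        out["differential_sensitivity_nominal"] = len(called_nominal & shifted) / len(shifted)
        out["differential_sensitivity_fdr"] = len(called_fdr & shifted) / len(shifted)
        out["differential_fdr_observed"] = (
            len(called_fdr - shifted) / len(called_fdr) if called_fdr else 0.0
        )

    if "enrichment" in results:
        enr = results["enrichment"].reset_index(drop=True)
        ranked = enr.sort_values(["fdr_q", "p_raw"], kind="stable")["set_id"].tolist()
        target = results.get("shifted_subpathway")
        if target is None:
            raise ValueError("recovery of enrichment needs results['shifted_subpathway']")
        out["enrichment_rank_of_shifted"] = ranked.index(target) + 1 if target in ranked else None
        row = enr[enr["set_id"] == target]
        out["enrichment_shifted_fdr_q"] = float(row["fdr_q"].iloc[0]) if len(row) else None
        out["enrichment_shifted_top_and_significant"] = bool(
            len(row) and out["enrichment_rank_of_shifted"] == 1 and row["fdr_q"].iloc[0] < 0.2
        )

    if "modules" in results:
        best_j, best_mod = 0.0, None
        for module in results["modules"]:
            if module.module_id == 0:
                continue
            mem = set(module.members)
            j = len(mem & set(truth.module_members)) / len(mem | set(truth.module_members))
            if j > best_j:
                best_j, best_mod = j, module
        out["module_jaccard"] = best_j
        out["module_sign_accuracy"] = float("nan")
        if best_mod is not None:
            common = [mid for mid in best_mod.members if mid in truth.module_members]
            if common:
                acc = np.mean(
                    [best_mod.submodule_signs[mid] == truth.module_members[mid] for mid in common]
                )
                out["module_sign_accuracy"] = float(max(acc, 1 - acc))
            out["module_p_perm"] = best_mod.p_perm

    if "scores" in results:
        scores = results["scores"]
        meta = results["metadata"]
        ind = meta.loc[scores.index, "individual_id"]
        bmi = truth.bmi.loc[ind].to_numpy()
        r_obs = float(np.corrcoef(scores.to_numpy(), bmi)[0, 1])
        out["score_bmi_r"] = r_obs
        out["score_bmi_r_empirical_composite"] = float(
            np.corrcoef(truth.composite.loc[ind], bmi)[0, 1]
        )
        out["score_bmi_r_planted"] = truth.r_planted_score
        out["score_bmi_r_gap"] = abs(r_obs - truth.r_planted_score)

    return out
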