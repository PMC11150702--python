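"""Config-driven orchestration of the full MR mediation analysis.

The run graph mirrors a two-sample MR mediation study: select instruments
per trait, estimate univariable effects (exposure→mediators, mediators→
outcome, exposure→outcome), screen mediators, fit one multivariable model
per adjustment set, compute PERM, then run the sensitivity battery on the
primary contrast (Cochran Q, MR-Egger, alternative estimators, MR-PRESSO,
leave-one-out, colocalization) and a reverse-direction MR.

All outputs are TSV tables plus a JSON manifest echoing seeds, thresholds
and stage counts; a re-run of an unchanged config reproduces the tables
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coloc import PPH4_SHARED_RULE, coloc_pipeline
from .exceptions import ConfigurationError, MrMediateError, NoInstrumentsError
from .harmonize import HarmonizedSet, harmonize
from .instruments import CLUMP_R2, CLUMP_WINDOW_BP, GWAS_P_THRESHOLD, select_instruments
from .mediation import mediation_report, report_frame, retained, screen_mediators
from .mvmr import mvmr_ivw
from .presso import presso
from .sumstats import LdPanel, SummaryDataset, read_sumstats
from .univariable import (
    MrEstimate,
    egger,
    ivw,
    leave_one_out,
    mode_estimators,
    weighted_median,
)

logger = logging.getLogger(__name__)


@dataclass
class TraitSpec:
    path: str
    trait_type: str = "continuous"
    column_map: dict | None = None
    effect_is_or: bool = False


@dataclass
class PipelineConfig:
    traits: dict[str, TraitSpec]
    exposure: str
    outcome: str
    mediators: list[str]
    ld_path: str | None
    output_dir: str
    adjustment_sets: list[list[str]] = field(default_factory=list)
    p_instrument: float = GWAS_P_THRESHOLD
    clump_r2: float = CLUMP_R2
    clump_window_bp: int = CLUMP_WINDOW_BP
    screen_alpha: float = 0.05
    coloc_half_window_bp: int = 500_000
    pph4_rule: float = PPH4_SHARED_RULE
    coloc_pairs: list[list[str]] = field(default_factory=list)
    palindrome_policy: str = "infer_by_eaf"
    eaf_ambiguity_band: float = 0.08
    ivw_model: str = "auto"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            traits = {
                name: TraitSpec(**spec) for name, spec in raw.pop("traits").items()
            }
            cfg = cls(traits=traits, **raw)
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed pipeline config {path}: {exc}") from exc
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        """Fail fast, before any computation."""
        roles = [self.exposure, self.outcome, *self.mediators]
        for name in roles:
            if name not in self.traits:
                raise ConfigurationError(f"role {name!r} has no trait entry")
        for s in self.adjustment_sets:
            for member in s:
                if member not in self.mediators:
                    raise ConfigurationError(
                        f"adjustment-set member {member!r} is not a declared mediator"
                    )
        if self.ld_path is None:
            raise ConfigurationError("config must name an LD source (ld_path)")
        base = base or Path(".")
        for name, spec in self.traits.items():
            p = Path(spec.path)
            resolved = p if p.is_absolute() else base / p
            if not resolved.exists():
                raise ConfigurationError(f"trait file for {name!r} not found: {resolved}")
            spec.path = str(resolved)
        ld = Path(self.ld_path)
        ld = ld if ld.is_absolute() else base / ld
        if not ld.exists():
            raise ConfigurationError(f"LD file not found: {ld}")
        self.ld_path = str(ld)


def _estimate_row(exposure: str, outcome: str, est: MrEstimate, het=None) -> dict:
    row = {
        "exposure": exposure,
        "outcome": outcome,
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "or": est.or_,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
    }
    if het is not None:
        row.update({"Q": het.q, "Q_df": het.df, "Q_p": het.pvalue})
    return row


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    A stage error on one contrast is recorded in the manifest and does not
    abort unrelated contrasts; an error on the primary exposure→outcome
    contrast re-raises after all reports are written.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    errors: list[dict] = []
    counts: dict[str, int | dict] = {}

    datasets: dict[str, SummaryDataset] = {}
    for name, spec in cfg.traits.items():
        datasets[name] = read_sumstats(
            spec.path,
            column_map=spec.column_map,
            trait_type=spec.trait_type,
            trait_name=name,
            effect_is_or=spec.effect_is_or,
        )
    ld = LdPanel.read(cfg.ld_path, window_bp=cfg.clump_window_bp)

    instruments: dict[str, SummaryDataset] = {}
    inst_rows = []
    for name, ds in datasets.items():
        if name == cfg.outcome:
            continue
        try:
            instruments[name] = select_instruments(
                ds, cfg.p_instrument, ld, cfg.clump_r2, cfg.clump_window_bp
            )
            inst_rows.append({"trait": name, "n_instruments": len(instruments[name])})
            logger.info("instruments %s: %d", name, len(instruments[name]))
        except MrMediateError as exc:
            errors.append({"stage": "instruments", "trait": name, "error": str(exc)})
    # reverse MR instruments from the outcome side
    try:
        instruments[cfg.outcome] = select_instruments(
            datasets[cfg.outcome], cfg.p_instrument, ld, cfg.clump_r2, cfg.clump_window_bp
        )
        inst_rows.append(
            {"trait": cfg.outcome, "n_instruments": len(instruments[cfg.outcome])}
        )
    except MrMediateError as exc:
        errors.append({"stage": "instruments", "trait": cfg.outcome, "error": str(exc)})
    _write(pd.DataFrame(inst_rows), outdir / "instruments.tsv")
    counts["instruments"] = {r["trait"]: r["n_instruments"] for r in inst_rows}

    def harmonized(exp_name: str, out_name: str) -> HarmonizedSet:
        if exp_name not in instruments:
            raise NoInstrumentsError(exp_name, cfg.p_instrument)
        return harmonize(
            [instruments[exp_name]],
            datasets[out_name],
            palindrome_policy=cfg.palindrome_policy,
            eaf_ambiguity_band=cfg.eaf_ambiguity_band,
        )

    # --- univariable stage -------------------------------------------------
    contrasts = (
        [(cfg.exposure, m) for m in cfg.mediators]
        + [(m, cfg.outcome) for m in cfg.mediators]
        + [(cfg.exposure, cfg.outcome)]
    )
    uni_rows, audit_frames = [], []
    primary_h: HarmonizedSet | None = None
    primary_error: Exception | None = None
    for exp_name, out_name in contrasts:
        try:
            h = harmonized(exp_name, out_name)
            est, het = ivw(h, model=cfg.ivw_model)
            uni_rows.append(_estimate_row(exp_name, out_name, est, het))
            audit = h.audit_frame()
            audit.insert(0, "contrast", f"{exp_name}->{out_name}")
            audit_frames.append(audit)
            if (exp_name, out_name) == (cfg.exposure, cfg.outcome):
                primary_h = h
        except MrMediateError as exc:
            errors.append(
                {"stage": "univariable", "contrast": f"{exp_name}->{out_name}", "error": str(exc)}
            )
            if (exp_name, out_name) == (cfg.exposure, cfg.outcome):
                primary_error = exc
    uni = pd.DataFrame(uni_rows)
    _write(uni, outdir / "univariable.tsv")
    if audit_frames:
        _write(pd.concat(audit_frames, ignore_index=True), outdir / "harmonization_audit.tsv")

    # --- mediator screen ---------------------------------------------------
    screen = screen_mediators(
        uni, cfg.exposure, cfg.outcome, cfg.mediators, alpha=cfg.screen_alpha
    )
    _write(
        pd.DataFrame(
            [
                {
                    "candidate": e.candidate,
                    "exposure_to_mediator_p": e.exposure_to_mediator_p,
                    "mediator_to_outcome_p": e.mediator_to_outcome_p,
                    "exposure_to_mediator_sig": e.exposure_to_mediator_sig,
                    "mediator_to_outcome_sig": e.mediator_to_outcome_sig,
                    "status": e.status,
                }
                for e in screen
            ]
        ),
        outdir / "screen.tsv",
    )
    counts["mediators_retained"] = len(retained(screen))

    # --- multivariable stage per adjustment set ----------------------------
    mvmr_rows = []
    adjusted: dict[tuple[str, ...], MrEstimate] = {}
    for adj_set in cfg.adjustment_sets:
        label = "+".join(adj_set)
        try:
            exposures = [cfg.exposure, *adj_set]
            # union of each exposure's instruments, re-clumped jointly by
            # the smallest p across exposures
            union: dict[str, object] = {}
            for name in exposures:
                for rec in instruments[name]:
                    prev = union.get(rec.snp_id)
                    if prev is None or rec.pvalue < prev.pvalue:
                        union[rec.snp_id] = rec
            joint = select_instruments(
                SummaryDataset("joint", "continuous", union.values()),
                p_threshold=cfg.p_instrument,
                ld=ld,
                r2_threshold=cfg.clump_r2,
                window_bp=cfg.clump_window_bp,
            )
            exp_sets = [
                SummaryDataset(
                    name,
                    datasets[name].trait_type,
                    (datasets[name][s] for s in joint.snp_ids if s in datasets[name]),
                )
                for name in exposures
            ]
            h = harmonize(
                exp_sets,
                datasets[cfg.outcome],
                palindrome_policy=cfg.palindrome_policy,
                eaf_ambiguity_band=cfg.eaf_ambiguity_band,
            )
            res = mvmr_ivw(h)
            for name, est in zip(res.exposures, res.estimates):
                row = _estimate_row(name, cfg.outcome, est, res.het)
                row["adjustment_set"] = label
                row["conditional_F"] = res.conditional_f[name]
                mvmr_rows.append(row)
            adjusted[tuple(adj_set)] = res[cfg.exposure]
        except MrMediateError as exc:
            errors.append({"stage": "mvmr", "adjustment_set": label, "error": str(exc)})
    _write(pd.DataFrame(mvmr_rows), outdir / "mvmr.tsv")

    # --- mediation report --------------------------------------------------
    total_row = uni[(uni["exposure"] == cfg.exposure) & (uni["outcome"] == cfg.outcome)]
    if len(total_row) and adjusted:
        total_est, _ = ivw(primary_h, model=cfg.ivw_model)
        try:
            med = mediation_report(total_est, adjusted, screen)
            _write(report_frame(med), outdir / "mediation.tsv")
        except MrMediateError as exc:
            errors.append({"stage": "mediation", "error": str(exc)})
    else:
        _write(report_frame([]), outdir / "mediation.tsv")

    # --- sensitivity battery on the primary contrast -----------------------
    sens_rows, loo_rows, presso_row = [], [], {}
    if primary_h is not None:
        h = primary_h
        try:
            slope, intercept, ehet = egger(h)
            sens_rows.append(_estimate_row(cfg.exposure, cfg.outcome, slope, ehet))
            sens_rows.append(_estimate_row(cfg.exposure, cfg.outcome, intercept))
            sens_rows.append(
                _estimate_row(
                    cfg.exposure, cfg.outcome,
                    weighted_median(h, n_boot=cfg.n_boot, seed=cfg.seed),
                )
            )
            for mode in ("weighted", "simple"):
                sens_rows.append(
                    _estimate_row(
                        cfg.exposure, cfg.outcome,
                        mode_estimators(h, mode=mode, n_boot=cfg.n_boot, seed=cfg.seed),
                    )
                )
        except MrMediateError as exc:
            errors.append({"stage": "sensitivity", "error": str(exc)})
        try:
            pres = presso(h, n_sim=cfg.presso_n_sim, seed=cfg.seed)
            presso_row = {
                "global_p": pres.global_p,
                "n_outliers": len(pres.outliers),
                "outliers": ",".join(pres.outliers),
                "beta_raw": pres.beta_raw,
                "beta_corrected": pres.beta_corrected,
                "distortion_p": pres.distortion_p,
                "n_sim": pres.n_sim,
                "seed": pres.seed,
            }
            if pres.corrected is not None:
                sens_rows.append(
                    _estimate_row(cfg.exposure, cfg.outcome, pres.corrected)
                    | {"method": "presso_corrected"}
                )
        except MrMediateError as exc:
            errors.append({"stage": "presso", "error": str(exc)})
        try:
            for entry in leave_one_out(h, model=cfg.ivw_model):
                loo_rows.append(
                    {
                        "omitted": entry.snp_id,
                        "beta": entry.estimate.beta,
                        "se": entry.estimate.se,
                        "ci_low": entry.estimate.ci_low,
                        "ci_high": entry.estimate.ci_high,
                        "flagged": entry.flagged,
                    }
                )
        except MrMediateError as exc:
            errors.append({"stage": "leave_one_out", "error": str(exc)})
    _write(pd.DataFrame(sens_rows), outdir / "sensitivity.tsv")
    _write(pd.DataFrame(loo_rows), outdir / "leave_one_out.tsv")
    _write(pd.DataFrame([presso_row] if presso_row else []), outdir / "presso.tsv")

    # --- colocalization ----------------------------------------------------
    coloc_rows, coloc_regions = [], []
    for pair in cfg.coloc_pairs:
        t1, t2 = pair
        try:
            res = coloc_pipeline(
                datasets[t1],
                datasets[t2],
                instruments[t1],
                half_window_bp=cfg.coloc_half_window_bp,
                shared_rule=cfg.pph4_rule,
            )
            coloc_rows.append(
                {
                    "trait_1": t1,
                    "trait_2": t2,
                    "n_regions": len(res.regions),
                    "mean_pph4": res.mean_pph4,
                    "shared_flag": res.shared_flag,
                }
            )
            rf = res.region_frame()
            rf.insert(0, "pair", f"{t1}|{t2}")
            coloc_regions.append(rf)
        except MrMediateError as exc:
            errors.append({"stage": "coloc", "pair": f"{t1}|{t2}", "error": str(exc)})
    _write(pd.DataFrame(coloc_rows), outdir / "coloc.tsv")
    if coloc_regions:
        _write(pd.concat(coloc_regions, ignore_index=True), outdir / "coloc_regions.tsv")

    # --- reverse MR --------------------------------------------------------
    reverse_rows = []
    reverse_significant = None
    try:
        h_rev = harmonized(cfg.outcome, cfg.exposure)
        est, het = ivw(h_rev, model=cfg.ivw_model)
        reverse_rows.append(_estimate_row(cfg.outcome, cfg.exposure, est, het))
        reverse_significant = bool(est.pvalue < 0.05)
    except MrMediateError as exc:
        errors.append({"stage": "reverse_mr", "error": str(exc)})
    _write(pd.DataFrame(reverse_rows), outdir / "reverse_mr.tsv")

    manifest = {
        "package_version": __version__,
        "config": {
            "exposure": cfg.exposure,
            "outcome": cfg.outcome,
            "mediators": cfg.mediators,
            "adjustment_sets": cfg.adjustment_sets,
            "p_instrument": cfg.p_instrument,
            "clump_r2": cfg.clump_r2,
            "clump_window_bp": cfg.clump_window_bp,
            "screen_alpha": cfg.screen_alpha,
            "coloc_half_window_bp": cfg.coloc_half_window_bp,
            "pph4_rule": cfg.pph4_rule,
            "palindrome_policy": cfg.palindrome_policy,
            "eaf_ambiguity_band": cfg.eaf_ambiguity_band,
            "ivw_model": cfg.ivw_model,
            "n_boot": cfg.n_boot,
            "presso_n_sim": cfg.presso_n_sim,
            "seed": cfg.seed,
        },
        "counts": counts,
        "reverse_mr_significant": reverse_significant,
        "errors": errors,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    if primary_error is not None:
        raise primary_error
    return outdir
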