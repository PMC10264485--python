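"""End-to-end orchestration: consistency scores -> surprisal -> measures ->
assembly -> interaction model, from a single YAML configuration.

A configuration names either real input files (embeddings, frequency list,
corpus, fixation report or self-paced table) or a ``synthetic`` block; the
stages then run in fixed order and every artifact lands in the output
directory stamped with the configuration hash and seed.  Reruns with the
same configuration and seed are bit-identical for all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, gam, measures, surprisal, synthetic
from .lexicon import build_lexicon, read_frequency_table, read_word2vec_text
from .osc import OscScorer

__all__ = ["PipelineError", "ValidationError", "run_pipeline", "load_config"]

log = logging.getLogger("lexread.pipeline")


class PipelineError(RuntimeError):
    """A stage failed after validation."""


class ValidationError(ValueError):
    """The configuration is malformed."""


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def _validate(cfg: dict) -> None:
    has_synth = "synthetic" in cfg and cfg["synthetic"] is not None
    has_inputs = "inputs" in cfg and cfg["inputs"] is not None
    if has_synth == has_inputs:
        raise ValidationError(
            "configuration must contain exactly one of 'synthetic' or 'inputs'"
        )
    mode = cfg.get("mode", "eyetracking")
    if mode not in ("eyetracking", "spr"):
        raise ValidationError(f"unknown mode {mode!r}")
    if has_inputs:
        required = {"embeddings", "frequencies", "corpus"}
        required.add("fixations" if mode == "eyetracking" else "spr")
        missing = required - set(cfg["inputs"])
        if missing:
            raise ValidationError(f"inputs block lacks {sorted(missing)}")
        for key, p in cfg["inputs"].items():
            if not Path(p).exists():
                raise ValidationError(f"input file for {key!r} not found: {p}")


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(
    config: dict | str | Path,
    seed: int | None = None,
    out: str | Path | None = None,
) -> dict:
    """Execute all stages; returns the run summary (also written to disk)."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    _validate(cfg)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg.setdefault("seed", 0)
    mode = cfg.get("mode", "eyetracking")
    dv = cfg.get("dv", "gaze" if mode == "eyetracking" else "rt")
    outdir = Path(out if out is not None else cfg.get("output_dir", "lexread_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    run_stamp = {"config_hash": _config_hash(cfg), "seed": cfg["seed"]}
    log.info("run %s -> %s", run_stamp, outdir)

    artifacts: dict[str, str] = {}
    try:
        # ------------------------------------------------------ inputs
        if cfg.get("synthetic") is not None:
            synth_cfg = synthetic.SyntheticConfig(
                seed=cfg["seed"], **cfg["synthetic"]
            )
            rng = np.random.default_rng(synth_cfg.seed)
            lex, truth = synthetic.make_lexicon(synth_cfg, rng)
            sentences, truth = synthetic.make_corpus(synth_cfg, truth, rng)
            freq_table = dict(
                zip(truth.lexicon_truth["word"], truth.lexicon_truth["frequency"])
            )
            if mode == "eyetracking":
                fixations, truth = synthetic.make_eyetracking_dataset(
                    synth_cfg, (lex, truth), (sentences, truth), rng
                )
                fixations.to_csv(outdir / "fixations.tsv", sep="\t", index=False)
                artifacts["fixations"] = "fixations.tsv"
                spr_table = None
            else:
                spr_table, truth = synthetic.make_spr_dataset(
                    synth_cfg, (lex, truth), (sentences, truth), rng
                )
                spr_table.to_csv(outdir / "spr.tsv", sep="\t", index=False)
                artifacts["spr"] = "spr.tsv"
                fixations = None
            with open(outdir / "corpus.txt", "w", encoding="utf-8") as fh:
                for s in sentences:
                    fh.write(" ".join(s) + "\n")
            artifacts["corpus"] = "corpus.txt"
        else:
            inputs = cfg["inputs"]
            vectors = read_word2vec_text(inputs["embeddings"])
            freq_table = read_frequency_table(inputs["frequencies"])
            lex = build_lexicon(vectors, freq_table)
            sentences = surprisal.read_corpus(inputs["corpus"])
            if mode == "eyetracking":
                fixations = measures.read_fixation_report(inputs["fixations"])
                spr_table = None
            else:
                spr_table = pd.read_csv(inputs["spr"], sep="\t")
                fixations = None

        # ------------------------------------------------------ OSC
        scorer = OscScorer().fit(lex)
        token_words = sorted({w for s in sentences for w in s})
        scoreable = [w for w in token_words if w in lex]
        osc_table = scorer.score_table(scoreable)
        osc_table.to_csv(outdir / "osc.tsv", sep="\t", index=False)
        artifacts["osc"] = "osc.tsv"

        # ------------------------------------------------------ surprisal
        lm_cfg = cfg.get("lm", {})
        lm = surprisal.NgramLanguageModel(
            order=int(lm_cfg.get("order", 3)),
            smoothing=lm_cfg.get("smoothing", "add_k"),
            k=float(lm_cfg.get("k", 1.0)),
            discount=float(lm_cfg.get("discount", 0.75)),
        ).fit(sentences)
        sup_table = lm.surprisal_table(sentences)
        sup_table = sup_table.assign(position=sup_table["position"].astype(int))
        sup_table.to_csv(outdir / "surprisal.tsv", sep="\t", index=False)
        artifacts["surprisal"] = "surprisal.tsv"

        # ------------------------------------------------------ measures
        if mode == "eyetracking":
            meas = measures.compute_measures(fixations)
            meas.to_csv(outdir / "measures.tsv", sep="\t", index=False)
            artifacts["measures"] = "measures.tsv"
        else:
            meas = spr_table

        # ------------------------------------------------------ assembly
        records, accounting = assembly.attach_covariates(
            meas, osc_table, sup_table, freq_table, dv=dv, mode=mode
        )
        thresholds = None
        if cfg.get("exclusions"):
            thresholds = (
                float(cfg["exclusions"]["lower_ms"]),
                float(cfg["exclusions"]["upper_ms"]),
            )
        records, report = assembly.apply_exclusions(
            records, mode=mode, thresholds=thresholds
        )
        records.to_csv(outdir / "records.tsv", sep="\t", index=False)
        report_dict = report.to_dict()
        report_dict["join_accounting"] = accounting
        report_dict.update(run_stamp)
        _write_json(report_dict, outdir / "exclusion_report.json")
        artifacts["records"] = "records.tsv"
        artifacts["exclusion_report"] = "exclusion_report.json"

        # ------------------------------------------------------ model
        model_cfg = cfg.get("model", {})
        spec = gam.ModelSpec(
            k_osc=int(model_cfg.get("k_osc", 5)),
            k_surprisal=int(model_cfg.get("k_surprisal", 5)),
            random_effects=bool(model_cfg.get("random_effects", True)),
        )
        comparison = gam.compare_forms(records, spec)
        final_fit = (
            comparison.tensor_fit
            if comparison.preferred_form == "tensor"
            else comparison.linear_fit
        )
        final_spec = gam.ModelSpec(
            **{**spec.__dict__, "interaction_form": comparison.preferred_form}
        )
        threshold = float(model_cfg.get("criticism_sd", 2.5))
        _, refit, removed = gam.model_criticism(
            records, model=final_fit, spec=final_spec, threshold=threshold
        )
        surface = comparison.tensor_fit.predict_surface(
            n_grid=int(model_cfg.get("surface_grid", 30))
        )
        surface.to_frame().to_csv(outdir / "surface.csv", index=False)
        artifacts["surface"] = "surface.csv"

        fit_summary = {
            "preferred_form": comparison.preferred_form,
            "comparison": comparison.to_dict(),
            "tensor": comparison.tensor_fit.summary(),
            "linear": comparison.linear_fit.summary(),
            "criticism": {
                "threshold_sd": threshold,
                "removed": removed,
                "refit": refit.summary(),
            },
            **run_stamp,
        }
        _write_json(fit_summary, outdir / "fit_summary.json")
        artifacts["fit_summary"] = "fit_summary.json"

        manifest = {
            **run_stamp,
            "mode": mode,
            "dv": dv,
            "artifacts": artifacts,
            "status": "ok",
        }
        _write_json(manifest, outdir / "manifest.json")
        return fit_summary
    except (ValidationError,):
        raise
    except Exception as e:
        # retain partial artifacts with a failure marker
        _write_json(
            {**run_stamp, "artifacts": artifacts, "status": "failed",
             "error": str(e)},
            outdir / "manifest.json",
        )
        raise PipelineError(str(e)) from e
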