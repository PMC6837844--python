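"""Pipeline orchestration: annotation -> scoring -> classifier -> contingency.

`run_pipeline` executes whichever stages the configuration enables and
writes per-stage tab-separated outputs plus a machine-readable JSON
summary. Every stochastic stage takes an explicit seed, recorded in the
summary; logs go to standard error so file outputs stay pipeable.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import balanced_auc, fit_logistic, jackknife, roc_points
from .contingency import class_summary, threshold_counts
from .coevolution import (
    build_evo_matrix,
    coverage_mask,
    fit_potts,
    read_alignment,
    sequence_weights,
)
from .ddg import (
    MLH1_DOMAINS,
    DomainDefinition,
    annotate_table,
    coverage_fraction,
    parse_replicate_table,
)
from .variants import (
    VariantTable,
    clinvar_binary_label,
    load_fixture_table,
    read_variant_tsv,
    write_variant_tsv,
)

__all__ = ["RunConfig", "run_pipeline"]

#: full-length protein and its modeled domains for the packaged fixture
MLH1_LENGTH = 756


@dataclass
class RunConfig:
    """Inputs, thresholds, and reproducibility settings for one run."""

    out_dir: str | Path = "results"
    variant_table: str | Path | None = None  # None -> packaged fixture
    replicate_table: str | Path | None = None
    alignment: str | Path | None = None
    alignment_query: str | None = None
    domains: DomainDefinition = field(default_factory=lambda: MLH1_DOMAINS)
    sequence_length: int = MLH1_LENGTH
    ddg_cap: float = 15.0
    min_neff_column: float = 50.0
    max_gap_fraction: float = 0.5
    n_resamples: int = 100
    seed: int = 0
    probability_threshold: float = 0.5


def _log(msg: str) -> None:
    print(f"[varstab] {msg}", file=sys.stderr)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _contingency_summary(table: VariantTable) -> dict:
    """The published count claims over the 69-variant panel, recomputed."""
    specs = {
        "ddg_gt3_ss_lt75": ("ddg>3", "steady_state<75"),
        "dme3_ss_gt70": ("dme=3", "steady_state>70"),
        "dme0_ss_gt70": ("dme=0", "steady_state>70"),
        "dme0_ddg_ge3": ("dme=0", "ddg>=3"),
    }
    out = {}
    for key, (sel, among) in specs.items():
        res = threshold_counts(table, sel, among)
        out[key] = {"numerator": res.n_both, "denominator": res.n_select}
    labels = {r.name: clinvar_binary_label(r.clinvar_class) for r in table}
    pos = [r for r in table if labels[r.name] == "positive"]
    neg = [r for r in table if labels[r.name] == "negative"]
    out["pathogenic_ss_lt70"] = {
        "numerator": sum(r.steady_state is not None and r.steady_state < 70 for r in pos),
        "denominator": sum(r.steady_state is not None for r in pos),
    }
    out["pathogenic_ddg_gt3"] = {
        "numerator": sum(r.ddg is not None and r.ddg > 3 for r in pos),
        "denominator": sum(r.ddg is not None for r in pos),
    }
    out["pathogenic_ddg_gt2"] = {
        "numerator": sum(r.ddg is not None and r.ddg > 2 for r in pos),
        "denominator": sum(r.ddg is not None for r in pos),
    }
    out["benign_ddg_gt1p5"] = {
        "numerator": sum(r.ddg is not None and r.ddg > 1.5 for r in neg),
        "denominator": sum(r.ddg is not None for r in neg),
    }
    out["n_pathogenic"] = len(pos)
    out["n_benign"] = len(neg)
    out["n_vus"] = len(table) - len(pos) - len(neg)
    out["n_variants"] = len(table)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write outputs under ``config.out_dir``.

    Always computes the saturation enumeration numbers and the contingency
    summary; ddG annotation, evolutionary scoring, and the two-feature
    classifier run when their inputs are configured and available.
    Returns the summary dict (also written as ``summary.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
    }

    # --- load variants
    if config.variant_table is None:
        table = load_fixture_table()
        summary["inputs"]["variant_table"] = "packaged fixture (69 variants)"
    else:
        p = Path(config.variant_table)
        if not p.exists():
            raise FileNotFoundError(f"variant table not found: {p}")
        table = read_variant_tsv(p)
        summary["inputs"]["variant_table"] = {"path": str(p), "sha256": _checksum(p)}
    _log(f"loaded {len(table)} variants ({table.provenance})")

    # --- ddG annotation
    if config.replicate_table is not None:
        p = Path(config.replicate_table)
        if not p.exists():
            raise FileNotFoundError(f"replicate table not found: {p}")
        try:
            matrix = parse_replicate_table(p, cap=config.ddg_cap)
            table = annotate_table(table, matrix)
        except Exception as exc:
            raise RuntimeError(f"stage ddg failed: {exc}") from exc
        summary["inputs"]["replicate_table"] = {"path": str(p), "sha256": _checksum(p)}
        matrix.to_long_frame().to_csv(out_dir / "ddg_matrix.tsv", sep="\t", index=False)
        _log(f"annotated ddG from {p} ({len(matrix.positions)} positions)")

    # --- evolutionary scoring
    if config.alignment is not None:
        p = Path(config.alignment)
        if not p.exists():
            raise FileNotFoundError(f"alignment not found: {p}")
        try:
            aln = read_alignment(p, config.alignment_query or "query")
            w = sequence_weights(aln)
            model = fit_potts(aln, weights=w)
            masked = coverage_mask(
                aln,
                weights=w,
                min_neff_column=config.min_neff_column,
                max_gap_fraction=config.max_gap_fraction,
            )
            evo = build_evo_matrix(model, aln.query, masked)
        except Exception as exc:
            raise RuntimeError(f"stage evoscore failed: {exc}") from exc
        summary["inputs"]["alignment"] = {"path": str(p), "sha256": _checksum(p)}
        summary["evo"] = {
            "n_sequences": aln.n_sequences,
            "n_eff": float(np.sum(w)),
            "n_masked_positions": len(masked),
            "converged": model.converged,
        }
        evo.to_long_frame().to_csv(out_dir / "evo_matrix.tsv", sep="\t", index=False)
        new_records = []
        for r in table:
            key = (r.position, r.mut_aa)
            if key in evo.normalized:
                new_records.append(
                    replace(
                        r,
                        evo_energy=evo.normalized[key],
                        evo_raw=evo.raw[key],
                    )
                )
            else:
                new_records.append(r)
        table = table.replace_records(new_records)
        _log(f"scored {len(evo.raw)} substitutions from {aln.n_sequences} sequences")

    # --- saturation enumeration numbers
    n_positions = len(config.domains.positions)
    summary["saturation"] = {
        "n_positions": n_positions,
        "n_variants": 19 * n_positions,
        "coverage_pct_raw": coverage_fraction(config.domains, config.sequence_length),
        "coverage_pct": round(
            coverage_fraction(config.domains, config.sequence_length)
        ),
    }

    # --- classifier (needs both features on labeled records)
    feats, labels, names = [], [], []
    for r in table:
        lab = clinvar_binary_label(r.clinvar_class)
        if lab == "excluded" or r.ddg is None or r.evo_energy is None:
            continue
        feats.append((r.ddg, r.evo_energy))
        labels.append(1 if lab == "positive" else 0)
        names.append(r.name)
    if len(feats) >= 3 and len(set(labels)) == 2:
        try:
            X = np.asarray(feats)
            y = np.asarray(labels)
            model = fit_logistic(X, y)
            jk = jackknife(X, y, threshold=config.probability_threshold)
            probs = model.predict_proba(X)
            roc = roc_points(probs, y)
            mean_auc, std_auc = balanced_auc(
                probs, y, n_resamples=config.n_resamples, seed=config.seed
            )
        except Exception as exc:
            raise RuntimeError(f"stage classify failed: {exc}") from exc
        summary["classifier"] = {
            "n": len(y),
            "w_ddg": model.w_ddg,
            "w_evo": model.w_evo,
            "intercept": model.intercept,
            "converged": model.converged,
            "separation": model.separation,
            "jackknife_accuracy": jk.accuracy,
            "jackknife_counts": jk.counts(),
            "auc": roc.auc,
            "balanced_auc_mean": mean_auc,
            "balanced_auc_std": std_auc,
            "n_resamples": config.n_resamples,
        }
        with open(out_dir / "classifier.txt", "w", encoding="utf-8") as fh:
            fh.write(f"w_ddg\t{model.w_ddg!r}\n")
            fh.write(f"w_evo\t{model.w_evo!r}\n")
            fh.write(f"intercept\t{model.intercept!r}\n")
            status = "separated" if model.separation else (
                "converged" if model.converged else "not-converged"
            )
            fh.write(f"status\t{status}\n")
        with open(out_dir / "jackknife.tsv", "w", encoding="utf-8") as fh:
            fh.write("variant\tcategory\n")
            for name, cat in zip(names, jk.categories):
                fh.write(f"{name}\t{cat or 'NA'}\n")
        _log(
            f"classifier on {len(y)} labeled variants: "
            f"jackknife accuracy {jk.accuracy:.3f}, AUC {roc.auc:.3f}"
        )
    else:
        summary["classifier"] = None
        _log("classifier skipped: needs ddG + evolutionary energy on labeled variants")

    # --- contingency summary
    summary["contingency"] = _contingency_summary(table)
    summary["dme_steady_state_summary"] = class_summary(table, "dme", "steady_state")

    write_variant_tsv(table, out_dir / "variants_annotated.tsv")
    with open(out_dir / "contingency.tsv", "w", encoding="utf-8") as fh:
        fh.write("claim\tnumerator\tdenominator\n")
        for key, val in summary["contingency"].items():
            if isinstance(val, dict):
                fh.write(f"{key}\t{val['numerator']}\t{val['denominator']}\n")
            else:
                fh.write(f"{key}\t{val}\t{len(table)}\n")
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
    _log(f"summary written to {out_dir / 'summary.json'}")
    return summary
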