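"""Pipeline driver: simulate -> transform -> screen -> infer -> classify -> summarize.

A run is fully described by one YAML-serializable config dict; re-running the
same config reproduces bit-identical outputs.  Every output TSV carries a
``#`` schema comment line, and a JSON manifest records versions, seeds,
parameters and per-output row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from . import io as mio
from .errors import ConfigurationError
from .infer import (
    BonferroniScheme,
    classify,
    infer_candidates,
    randomize_and_compare,
    rank_genes,
    results_to_frame,
    tally_positive_significant,
)
from .screen import ScreenConfig, candidates_to_frame, run_screen_all
from .synthetic import (
    SyntheticTruth,
    cohort_config_from_dict,
    cohort_config_to_dict,
    generate_cohort,
    generate_deg_table,
    pre_post_design,
)
from .transforms import TRANSFORMS

log = logging.getLogger("mima.pipeline")

DEFAULT_CONFIG: dict = {
    "cohort": {},            # CohortConfig fields (see synthetic.CohortConfig)
    "screen": {},            # ScreenConfig fields
    "alpha": 0.05,
    "transforms": list(TRANSFORMS),
    "deg_mode": "all",       # "all" (every gene is eligible) | "differential"
    "n_pre_timepoints": 3,
    "nullcheck": True,
    "n_randomizations": 1,
    "outdir": "mima_run",
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    return cfg


def _deg_lists(expression, mode: str, n_pre: int) -> dict[str, list[str]]:
    if mode == "all":
        return {ct: list(expr.genes) for ct, expr in expression.items()}
    if mode == "differential":
        degs = {}
        for ct, expr in expression.items():
            table = generate_deg_table(expr, pre_post_design(expr, n_pre=n_pre))
            degs[ct] = table.loc[table["is_deg"], "gene"].tolist()
        return degs
    raise ConfigurationError(f"unknown deg_mode {mode!r}")


def _truth_frame(truth: SyntheticTruth):
    import pandas as pd

    return pd.DataFrame(
        [
            (p.cell_type, p.gene, p.microbe, p.domain, p.rank, p.sign)
            for p in truth.planted_pairs
        ],
        columns=["cell_type", "gene", "microbe", "domain", "rank", "sign"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the full analysis graph on a simulated cohort; returns the manifest."""
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    cohort_cfg = cohort_config_from_dict(cfg["cohort"])
    screen_cfg = ScreenConfig(**cfg["screen"])
    transforms = tuple(cfg["transforms"])

    stage = "simulate"
    try:
        expression, microbes, truth = generate_cohort(cohort_cfg)
        for ct, expr in expression.items():
            mio.write_matrix(expr, outdir / f"expression_{ct}.tsv")
        for (domain, rank), m in microbes.items():
            mio.write_matrix(m, outdir / f"microbes_{domain}_{rank}.tsv")
        mio.write_table(_truth_frame(truth), outdir / "truth.tsv")

        stage = "degs"
        degs = _deg_lists(expression, cfg["deg_mode"], cfg["n_pre_timepoints"])

        stage = "screen"
        candidates = run_screen_all(expression, microbes, degs, screen_cfg, transforms=transforms)
        mio.write_table(candidates_to_frame(candidates), outdir / "candidates.tsv")

        stage = "infer"
        scheme = BonferroniScheme.from_inputs(microbes, degs, alpha=cfg["alpha"])
        results = classify(infer_candidates(expression, microbes, candidates), scheme)
        results_frame = results_to_frame(results)
        mio.write_table(results_frame, outdir / "associations.tsv")

        stage = "nullcheck"
        if cfg["nullcheck"]:
            comparison = randomize_and_compare(
                expression, microbes, degs, screen_cfg,
                alpha=cfg["alpha"],
                n_randomizations=cfg["n_randomizations"],
                seed=cohort_cfg.seed + 1,
                transforms=transforms,
            )
            mio.write_table(comparison.to_frame(), outdir / "null_comparison.tsv")

        stage = "summaries"
        tally = tally_positive_significant(results, cell_types=cohort_cfg.cell_types)
        import pandas as pd

        mio.write_table(
            pd.DataFrame(sorted(tally.items()), columns=["cell_type", "n_positive_bonf_005"]),
            outdir / "tally.tsv",
        )
        ranked = rank_genes(results)
        ranked_rows = []
        for ct in sorted(ranked):
            frame = ranked[ct].copy()
            frame.insert(0, "cell_type", ct)
            ranked_rows.append(frame)
        ranked_frame = (
            pd.concat(ranked_rows, ignore_index=True)
            if ranked_rows
            else pd.DataFrame(columns=["cell_type", "gene", "n_bonf_020", "n_nominal"])
        )
        mio.write_table(ranked_frame, outdir / "ranked_genes.tsv")

        stage = "recovery"
        truth_keys = truth.pair_keys()
        recovered = {
            (r.cell_type, r.gene, r.microbe, r.domain, r.rank)
            for r in results
            if r.nominal
        }
        recovery = {
            "n_planted": len(truth_keys),
            "n_recovered_nominal": len(truth_keys & recovered),
        }
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "version": __version__,
        "config": {**cfg, "cohort": cohort_config_to_dict(cohort_cfg)},
        "seed": cohort_cfg.seed,
        "stages": ["simulate", "degs", "screen", "infer"]
        + (["nullcheck"] if cfg["nullcheck"] else [])
        + ["summaries", "recovery"],
        "recovery": recovery,
        "outputs": {
            name: {
                "rows": sum(1 for line in (outdir / name).open() if not line.startswith("#")) - 1,
                "sha256": _sha256(outdir / name),
            }
            for name in outputs
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
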