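"""End-to-end orchestration: DEG -> TF logics -> RCA -> association -> GRN.

Every stage writes a plain TSV into the output directory; a JSON manifest
records the package version, the seed, the stage order and a SHA-256
checksum of every output, so a rerun with the same config and seed can be
verified byte-for-byte. On a stage failure the outputs written so far are
kept and a ``<stage>.partial`` marker names the failing stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .association import target_set_enrichment
from .deg import compute_de, filter_degs
from .io import RunConfig, read_binding, read_expression, read_gmt, read_regulator_targets
from .logictrn import fits_to_frame, infer_trn
from .networks import assemble_grn, export_network
from .rca import run_rca

logger = logging.getLogger(__name__)

STAGES = ("deg", "logictrn", "rca", "associate", "grn")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order; returns the output directory."""
    required = {"expression": config.expression, "binding": config.binding,
                "regulator_targets": config.regulator_targets}
    if config.gene_sets:
        required["gene_sets"] = config.gene_sets
    for name, path in required.items():
        if not path or not Path(path).is_file():
            raise FileNotFoundError(f"{name} input not readable: {path!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    outputs: dict[str, Path] = {}
    current = "deg"
    try:
        expr = read_expression(config.expression, scale=config.expression_scale)
        binding = read_binding(config.binding)
        maps = read_regulator_targets(config.regulator_targets)

        degs_all = compute_de(expr, config.group_a, config.group_b,
                              adjust=config.adjust_p)
        degs = filter_degs(degs_all, fc_min=config.fc_min, p_max=config.p_max)
        outputs["degs"] = out / "degs.tsv"
        degs.to_tsv(outputs["degs"])
        logger.info("deg: %d/%d genes pass", len(degs), len(degs_all))

        current = "logictrn"
        fits = infer_trn(expr, binding, degs, conf_min=config.conf_min,
                         t_m=config.t_m, decay=config.decay)
        outputs["logics"] = out / "logics.tsv"
        fits_to_frame(fits).to_csv(outputs["logics"], sep="\t", index=False)

        current = "rca"
        ncrna_maps = [m for m in maps if m.regulator_class in ("miRNA", "lncRNA")]
        rca_results = {}
        if ncrna_maps:
            rca_results = run_rca(
                expr, degs, ncrna_maps, n_perm=config.n_perm, alpha=config.alpha,
                seed=config.seed, z_method=config.z_method,
                z_from_degs=config.z_from_degs,
            )
        for direction in ("up", "down"):
            path = out / f"rca_{direction}.tsv"
            outputs[f"rca_{direction}"] = path
            if direction in rca_results:
                rca_results[direction].to_frame(alpha=config.alpha).to_csv(
                    path, sep="\t", index=False)
            else:
                pd.DataFrame(columns=["gene", "regulator", "strength", "p",
                                      "significant", "circular_flag", "direction"]
                             ).to_csv(path, sep="\t", index=False)

        current = "associate"
        target_sets: dict[str, set] = {}
        for fit in fits:
            for tf in fit.logic.operands:
                target_sets.setdefault(tf, set()).add(fit.gene_id)
        for res in rca_results.values():
            for i, g in enumerate(res.gene_ids):
                for j, r in enumerate(res.regulator_ids):
                    if res.p_values[i, j] < config.alpha:
                        target_sets.setdefault(r, set()).add(g)
        universe = set(expr.gene_ids)
        outputs["association"] = out / "association.tsv"
        if config.gene_sets:
            refs = read_gmt(config.gene_sets, universe=universe)
            assoc = target_set_enrichment(target_sets, refs, universe,
                                          gap=config.gap)
        elif len(target_sets) >= 2:
            from .io import GeneSetCollection

            refs = GeneSetCollection(dict(target_sets), universe=universe)
            assoc = target_set_enrichment(target_sets, refs, universe,
                                          gap=config.gap)
        else:
            assoc = pd.DataFrame(columns=["target_set", "reference_set", "n_a",
                                          "n_b", "n_overlap", "universe_n",
                                          "jaccard", "simpson", "p", "q"])
        assoc.to_csv(outputs["association"], sep="\t", index=False)

        current = "grn"
        classes = {m.regulator_id: m.regulator_class for m in maps}
        grn = assemble_grn(fits, list(rca_results.values()), classes, degs,
                           stage_label="run", alpha=config.alpha)
        for p in export_network(grn, out / "grn", format="tsv"):
            outputs[p.stem] = p
        outputs["grn_json"] = out / "grn.json"
        export_network(grn, outputs["grn_json"], format="json")
    except Exception:
        (out / f"{current}.partial").write_text(
            f"pipeline aborted during stage {current}\n")
        logger.error("pipeline aborted during stage %r", current)
        raise

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(STAGES),
        "config": dataclasses.asdict(config),
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
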