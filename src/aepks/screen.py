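"""Screening-statistics bookkeeping and pipeline orchestration.

A resolved/screened population is tallied into the three phenotype
classes used in plate screens of accelerated-evolution progeny:
producers of the parent compound (revertants), producers of a new
analogue, and non-producers. Percentages follow the two reporting
styles of such screens: one decimal place for populations above 100,
nearest integer for small control experiments; both round half up.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from .errors import ValidationError
from . import io as cluster_io
from .assembly import predict_product, architecture_table
from .junctions import detect_junctions, junctions_to_dataframe
from .simulate import PHENOTYPE_OF_CLASS, SimulationParams, simulate_population

__all__ = ["ScreenTally", "tally", "tally_events", "run_pipeline"]

PHENOTYPES = ("parent_producer", "new_analogue", "non_producer")

log = logging.getLogger("aepks")


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ScreenTally:
    """Exact integer counts per phenotype class and their percentages
    (rounded per the population-size convention)."""

    n_total: int
    n_parent_producer: int
    n_new_analogue: int
    n_non_producer: int
    percentages: dict[str, float]

    def __post_init__(self):
        if self.n_parent_producer + self.n_new_analogue + self.n_non_producer != self.n_total:
            raise ValidationError("class counts do not sum to n_total")


def tally(labels) -> ScreenTally:
    """Tally an iterable of phenotype labels (permutation-invariant)."""
    counts = {k: 0 for k in PHENOTYPES}
    n = 0
    for lab in labels:
        if lab not in counts:
            raise ValidationError(f"unknown phenotype label {lab!r}")
        counts[lab] += 1
        n += 1
    ndigits = 1 if n > 100 else 0
    pct = {
        k: _round_half_up(100.0 * v / n, ndigits) if n else 0.0
        for k, v in counts.items()
    }
    return ScreenTally(
        n_total=n,
        n_parent_producer=counts["parent_producer"],
        n_new_analogue=counts["new_analogue"],
        n_non_producer=counts["non_producer"],
        percentages=pct,
    )


def tally_events(event_classes) -> ScreenTally:
    """Tally simulator event classes via the phenotype map
    (revertant -> parent producer, in-frame rearrangement -> new
    analogue, frameshift/stop -> non-producer)."""
    return tally(PHENOTYPE_OF_CLASS[c] for c in event_classes)


# --- pipeline orchestration ------------------------------------------


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run one pipeline stage (simulate | detect | predict) from a
    config mapping or YAML/JSON file; write deterministic TSV/JSON
    outputs plus a run log echoing seed and parameters."""
    if not isinstance(config, dict):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode")
    seed = int(config.get("seed", 0))
    cluster = cluster_io.load_cluster(config["cluster"])
    log.info("pipeline mode=%s seed=%d cluster=%s", mode, seed, cluster.name)
    outputs: dict = {"mode": mode, "seed": seed}

    try:
        if mode == "simulate":
            from .synthetic import generate_integrant

            gene_id, span = config["homology"].split(":")
            s, e = (int(x) for x in span.split("-"))
            state = generate_integrant(cluster, gene_id, (s, e), seed=seed)
            params = SimulationParams(
                window_nt=int(config.get("window", 100)),
                step_nt=int(config.get("step", config.get("window", 100))),
                min_identity=float(config.get("min_identity", 0.8)),
                allow_expansion=bool(config.get("allow_expansion", True)),
            )
            summary = simulate_population(
                state, int(config.get("n", 100)), params=params, seed=seed
            )
            events_path = outdir / "events.tsv"
            summary.events.to_csv(events_path, sep="\t", index=False)
            st = tally_events(summary.events["event_class"])
            summary_path = outdir / "summary.json"
            payload = {
                "n": summary.n,
                "seed": seed,
                "event_counts": summary.counts,
                "event_fractions": summary.fractions,
                "phenotype_counts": summary.phenotype_counts,
                "phenotype_fractions": summary.phenotype_fractions,
                "percentages": st.percentages,
                "params": {
                    "window_nt": params.window_nt,
                    "min_identity": params.min_identity,
                    "min_identical_run": params.min_identical_run,
                },
            }
            summary_path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
            outputs.update(events=str(events_path), summary=str(summary_path), tally=st)
        elif mode == "detect":
            from .model import HybridRecord, translate_gene

            rows = []
            for seq_id, nt in cluster_io.read_fasta(config["hybrid"]):
                hyb = HybridRecord(
                    seq_id=seq_id, nt_seq=nt, aa_seq=translate_gene(nt, internal_stop="keep")
                )
                js = detect_junctions(
                    hyb, cluster, window_aa=int(config.get("window", 30))
                )
                rows.append(junctions_to_dataframe(js, seq_id=seq_id))
            import pandas as pd

            table = pd.concat(rows, ignore_index=True) if rows else junctions_to_dataframe([])
            out_path = outdir / "junctions.tsv"
            table.to_csv(out_path, sep="\t", index=False)
            outputs.update(junctions=str(out_path), table=table)
        elif mode == "predict":
            pred = predict_product(
                cluster, starter_carbons=int(config.get("starter_carbons", 7))
            )
            arch = architecture_table(cluster)
            out_path = outdir / "product.json"
            payload = {
                "n_extension_modules": pred.n_extension_modules,
                "starter_carbons": pred.starter_carbons,
                "backbone_carbons": pred.backbone_carbons,
                "alpha_substituents": pred.alpha_substituents,
                "beta_states": pred.beta_states,
                "viable": pred.viable,
                "reasons": pred.reasons,
            }
            out_path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
            arch_path = outdir / "architecture.tsv"
            arch.to_csv(arch_path, sep="\t", index=False)
            outputs.update(product=str(out_path), architecture=str(arch_path), prediction=pred)
        else:
            raise ValidationError(f"unknown pipeline mode {mode!r}")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {mode!r} failed on cluster {cluster.name!r}: {exc}"
        ) from exc

    runlog = outdir / "run.json"
    runlog.write_text(
        json.dumps(
            {"mode": mode, "seed": seed, "config": {k: str(v) for k, v in config.items()}},
            sort_keys=True,
            indent=2,
        )
        + "\n"
    )
    outputs["run_log"] = str(runlog)
    return outputs
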