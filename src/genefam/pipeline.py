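"""End-to-end pipeline: simulate -> structure -> ancestral states ->
reconciliation -> tandem/copy-number stats -> expression.

Stages hand data to each other through plain files in the output
directory, so every stage is independently runnable and resumable, and a
run is reproducible byte-for-byte from its config and seed.  The run
report collects the family-level tallies (Type 1/2/3 event totals, D, L,
D/L score, tandem arrays, expression table) in one JSON document.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from Bio import AlignIO

import importlib

gio = importlib.import_module("genefam.io")
qpcr = importlib.import_module("genefam.qpcr")
grec = importlib.import_module("genefam.reconcile")
gsim = importlib.import_module("genefam.simulate")
gstats = importlib.import_module("genefam.stats")
from .parsimony import reconstruct_structure_history
from .structure import (
    CharacterState,
    classify_events,
    compute_intron_profile,
    encode_character_state,
    project_introns,
)
from .trees import RootedTree

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("genefam")

_STAGES = ["simulate", "structure", "asr", "reconcile", "tandem", "copycorr", "expression"]

_STAGE_KEYS = {
    "simulate": {
        "n_species", "dup_rate", "loss_rate", "type1_rate", "type2_rate",
        "type3_rate", "ct_noise_sd", "fold_changes", "n_scattered", "n_arrays",
    },
    "structure": {"genes", "alignment", "reference", "tolerance"},
    "asr": {"tree", "states", "unknown_as_missing"},
    "reconcile": {"gene_tree", "species_tree", "w_dup", "w_loss"},
    "tandem": {"loci", "max_intervening", "max_gap_bp"},
    "copycorr": {"summaries"},
    "expression": {"ct", "reference_gene", "calibrator"},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    outdir: Path
    seed: int = 0
    stages: list = field(default_factory=lambda: list(_STAGES))
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {_STAGES}")
        for stage, options in self.params.items():
            if stage not in _STAGES:
                raise ValueError(f"unknown config section {stage!r}")
            bad = set(options) - _STAGE_KEYS[stage]
            if bad:
                raise ValueError(f"unknown keys {sorted(bad)} in section {stage!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known_top = {"outdir", "seed", "stages"}
        params = {k: v for k, v in raw.items() if k not in known_top}
        return cls(
            outdir=raw.get("outdir", "genefam_run"),
            seed=int(raw.get("seed", 0)),
            stages=raw.get("stages", list(_STAGES)),
            params=params,
        )

    def serialized(self) -> str:
        return yaml.safe_dump(
            {
                "outdir": str(self.outdir),
                "seed": self.seed,
                "stages": list(self.stages),
                **{k: v for k, v in self.params.items()},
            },
            sort_keys=True,
        )

    def stage_seed(self, stage: str) -> int:
        # derive a per-stage seed from the top-level seed, stable across runs
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a report.

    Outputs land in ``config.outdir``; the report (also returned) is
    written to ``report.json`` and the log to ``run.log``.  Any stage
    error aborts the run with :class:`PipelineError` naming the stage; a
    FAILED marker file is left next to the partial outputs.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    config_text = config.serialized()
    report: dict = {
        "config": config_text,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
    }
    logger.info("run start; seed=%d; stages=%s", config.seed, ",".join(config.stages))
    try:
        for stage in _STAGES:
            if stage not in config.stages:
                continue
            runner = globals()[f"_stage_{stage}"]
            logger.info("stage %s start", stage)
            report["stages"][stage] = runner(config, out)
            logger.info("stage %s done", stage)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        logger.exception("stage failed")
        raise PipelineError(f"pipeline failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def _opts(config: RunConfig, stage: str) -> dict:
    return dict(config.params.get(stage, {}))


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    opts = _opts(config, "simulate")
    sim_config = gsim.SimulationConfig(
        seed=config.stage_seed("simulate"),
        **{k: v for k, v in opts.items() if k not in ("n_scattered", "n_arrays")},
    )
    rng_seed = sim_config.seed
    species_tree = gsim.simulate_species_tree(sim_config.n_species, rng_seed)
    gene_tree, fam_truth = gsim.simulate_gene_family(
        species_tree, sim_config.dup_rate, sim_config.loss_rate, rng_seed + 1
    )
    struct = gsim.simulate_structure_evolution(
        gene_tree,
        sim_config.type1_rate,
        sim_config.type2_rate,
        sim_config.type3_rate,
        seed=rng_seed + 2,
    )
    loci, true_arrays = gsim.simulate_tandem_loci(
        n_scattered=opts.get("n_scattered", 4),
        n_arrays=opts.get("n_arrays", 2),
        seed=rng_seed + 3,
    )
    ct = gsim.simulate_ct_data(
        fold_changes=sim_config.fold_changes,
        ct_noise_sd=sim_config.ct_noise_sd,
        seed=rng_seed + 4,
        genes=("GeneX",),
    )

    species_tree.to_file(out / "species_tree.nwk")
    gene_tree.to_file(out / "gene_tree.nwk")
    models = [struct.reference_model] + [
        struct.leaf_models[k] for k in sorted(struct.leaf_models)
    ]
    gio.write_exon_table(models, out / "gene_models.tsv")
    AlignIO.write(struct.alignment, str(out / "alignment.fasta"), "fasta")
    with open(out / "loci.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "species", "chromosome", "start", "end", "family_member", "gene_rank"])
        for locus in loci:
            writer.writerow([
                locus.gene_id, locus.species, locus.chromosome, locus.start,
                locus.end, int(locus.family_member), locus.gene_rank,
            ])
    ct.wells.to_csv(out / "ct.tsv", sep="\t", index=False)

    truth = {
        "n_duplications": fam_truth.n_duplications,
        "n_losses": fam_truth.n_losses,
        "n_resampled": fam_truth.n_resampled,
        "true_arrays": true_arrays,
        "leaf_states": {
            label: encode_character_state(code).value
            for label, code in struct.leaf_codes.items()
        },
        "branch_event_totals": _event_totals(
            [e for events in struct.branch_events.values() for e in events]
        ),
        # per-gene totals: each gene's cumulative events along its lineage
        # (an event on a shared branch counts once per descendant gene)
        "per_gene_event_totals": _event_totals(
            [
                e
                for leaf in struct.gene_tree.leaves()
                for e in struct.true_event_multiset(leaf.label)
            ]
        ),
        "fold_changes": sim_config.fold_changes,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return {
        "n_species": sim_config.n_species,
        "n_genes": len(struct.leaf_models),
        **truth,
    }


def _event_totals(events) -> dict:
    totals = {"Type1": 0, "Type2": 0, "Type3": 0}
    for event in events:
        totals[event.event_type.value] += 1
    return totals


def _stage_structure(config: RunConfig, out: Path) -> dict:
    opts = _opts(config, "structure")
    genes_path = opts.get("genes", out / "gene_models.tsv")
    aln_path = opts.get("alignment", out / "alignment.fasta")
    reference = opts.get("reference", "ancestor")
    tolerance = int(opts.get("tolerance", 0))

    models = {m.gene_id: m for m in gio.read_gene_models(genes_path)}
    if reference not in models:
        raise ValueError(f"reference gene {reference!r} not among gene models")
    alignment = AlignIO.read(str(aln_path), "fasta")
    ref_profile = compute_intron_profile(models[reference])

    rows = []
    totals = {"Type1": 0, "Type2": 0, "Type3": 0}
    for gene_id, model in sorted(models.items()):
        if gene_id == reference:
            continue
        profile = compute_intron_profile(model)
        code = project_introns(profile, alignment, ref_profile, tolerance=tolerance)
        state = encode_character_state(code)
        events = [] if code.unresolved else classify_events(code)
        for event in events:
            totals[event.event_type.value] += 1
        rows.append({
            "gene_id": gene_id,
            "n_introns": len(profile.introns),
            "present_mask": "".join(
                "1" if p else "0" for p in code.ancestral_intron_present
            ),
            "novel_exon2_intron": int(code.novel_exon2_intron),
            "unresolved": int(code.unresolved),
            "phases": ",".join(str(p) for p in profile.phases),
            "events": ";".join(
                f"{e.event_type.value}{e.intron_indices}" for e in events
            ),
            "state": state.value,
        })
    with open(out / "structure_report.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    with open(out / "states.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "state"])
        for row in rows:
            writer.writerow([row["gene_id"], row["state"]])
    return {"n_genes": len(rows), "event_totals": totals}


def _stage_asr(config: RunConfig, out: Path) -> dict:
    opts = _opts(config, "asr")
    tree_path = opts.get("tree", out / "gene_tree.nwk")
    states_path = opts.get("states", out / "states.tsv")
    tree = RootedTree.from_file(tree_path)

    from .structure import state_to_code, N_ANCESTRAL_INTRONS, StructureCode

    states: dict[str, CharacterState] = {}
    with open(states_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            states[row["gene_id"]] = CharacterState(row["state"])
    codes = []
    for gene_id, state in states.items():
        code = state_to_code(state, gene_id=gene_id)
        if code is None:
            code = StructureCode(
                gene_id, (True,) * N_ANCESTRAL_INTRONS, unresolved=True
            )
        codes.append(code)
    history = reconstruct_structure_history(
        codes, tree, unknown_as_missing=bool(opts.get("unknown_as_missing", False))
    )
    _label_internal(tree)
    with open(out / "asr_nodes.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node", "state", "frequency"])
        for node, freqs in history.reconstruction.node_state_frequencies.items():
            for state, frequency in sorted(freqs.items(), key=lambda kv: kv[0].value):
                writer.writerow([node.label, state.value, f"{frequency:.6f}"])
    with open(out / "asr_branch_events.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node", "parent_state", "child_state", "events", "irregular"])
        for be in history.branch_events:
            writer.writerow([
                be.node.label,
                be.parent_state.value,
                be.child_state.value,
                ";".join(f"{e.event_type.value}{e.intron_indices}" for e in be.events),
                int(be.irregular),
            ])
    root_state = history.node_states[tree.root]
    return {
        "parsimony_length": history.reconstruction.parsimony_length,
        "mpr_count": history.reconstruction.mpr_count,
        "root_state": root_state.value,
        "n_branch_changes": len(history.branch_events),
    }


def _label_internal(tree: RootedTree) -> None:
    i = 0
    for node in tree.preorder():
        if not node.is_leaf and node.label is None:
            i += 1
            node.label = f"node{i}"


def _stage_reconcile(config: RunConfig, out: Path) -> dict:
    opts = _opts(config, "reconcile")
    gene_path = opts.get("gene_tree", out / "gene_tree.nwk")
    species_path = opts.get("species_tree", out / "species_tree.nwk")
    for path in (gene_path, species_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"tree file not found: {path}")
    gene_tree = RootedTree.from_file(gene_path)
    species_tree = grec.resolve_polytomies(RootedTree.from_file(species_path))
    gene_tree = grec.resolve_polytomies(gene_tree)
    result = grec.reconcile(
        gene_tree,
        species_tree,
        w_dup=float(opts.get("w_dup", grec.DEFAULT_DUP_WEIGHT)),
        w_loss=float(opts.get("w_loss", grec.DEFAULT_LOSS_WEIGHT)),
    )
    summary = {
        "n_duplications": result.n_duplications,
        "n_losses": result.n_losses,
        "dl_score": result.dl_score,
        "duplication_nodes": result.duplication_labels(),
        "per_branch_losses": {
            (node.label or "?"): count for node, count in result.per_branch_losses.items()
        },
    }
    (out / "reconciliation.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _stage_tandem(config: RunConfig, out: Path) -> dict:
    opts = _opts(config, "tandem")
    loci_path = opts.get("loci", out / "loci.tsv")
    max_intervening = int(opts.get("max_intervening", 1))
    max_gap_bp = int(opts.get("max_gap_bp", 100_000))
    loci = []
    with open(loci_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            loci.append(
                gstats.GeneLocus(
                    gene_id=row["gene_id"],
                    species=row["species"],
                    chromosome=row["chromosome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    family_member=bool(int(row.get("family_member", 1))),
                    gene_rank=(
                        int(row["gene_rank"])
                        if row.get("gene_rank") not in (None, "", "NA")
                        else None
                    ),
                )
            )
    arrays = gstats.detect_tandem_arrays(
        loci, max_intervening=max_intervening, max_gap_bp=max_gap_bp
    )
    with open(out / "tandem_arrays.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["array", "genes"])
        for i, array in enumerate(arrays, start=1):
            writer.writerow([i, ",".join(array)])
    return {
        "criterion": {"max_intervening": max_intervening, "max_gap_bp": max_gap_bp},
        "n_arrays": len(arrays),
        "arrays": arrays,
    }


def _stage_copycorr(config: RunConfig, out: Path) -> dict:
    opts = _opts(config, "copycorr")
    summaries_path = opts.get("summaries")
    if summaries_path is None:
        summaries = gstats.demo_species_summaries()
        source = "synthetic demonstration table"
    else:
        summaries = []
        with open(summaries_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                summaries.append(
                    gstats.SpeciesSummary(
                        species=row["species"],
                        copy_number=int(row["copy_number"]),
                        genome_size_mb=float(row["genome_size_mb"]),
                        wgd_events=int(row["wgd_events"]),
                    )
                )
        source = str(summaries_path)
    correlations = gstats.copy_number_correlations(summaries)
    payload = {"source": source, "correlations": correlations}
    (out / "copy_number_correlations.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    return payload


def _stage_expression(config: RunConfig, out: Path) -> dict:
    opts = _opts(config, "expression")
    ct_path = opts.get("ct", out / "ct.tsv")
    reference = opts.get("reference_gene", "actin")
    calibrator = opts.get("calibrator", "control")
    data = gio.read_ct_table(ct_path).with_design(reference, calibrator)
    table = qpcr.expression_table(data)
    table.to_csv(out / "expression.tsv", sep="\t", index=False)
    folds = {
        f"{row.gene}:{row.sample}": round(row.fold_change, 4)
        for row in table.itertuples()
    }
    return {"n_rows": len(table), "fold_changes": folds}
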