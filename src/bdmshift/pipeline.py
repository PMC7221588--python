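"""End-to-end pipeline: tree fitting, ancestors, branch test, motif report.

Stages run in the analysis order the test requires — (1) branch lengths on
the given or NJ topology, (2) marginal ancestral reconstruction, (3) the
focal-branch BDM contrast, (4) motif scanning — each persisting its outputs
before the next starts, with a run manifest recording input digests and every
resolved parameter so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ancestral import ancestral_sequence_report, marginal_ancestral
from .bdm import bdm_branch_test, derive_bdm, fisher_one_tail, read_bdm_matrix
from .engine import nj_tree, optimize_branch_lengths, protein_distance
from .io import (
    read_fasta_alignment,
    read_newick,
    to_newick,
    write_fasta,
)
from .models import discretize_gamma, load_model
from .motifs import clade_motif_table, conservation_counts, conserved_column_report, scan_motif


class ConfigError(ValueError):
    pass


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path, out_dir) -> Path:
    """Execute the configured stages; returns the output directory.

    The config is a flat YAML mapping.  A config with only ``fisher_table``
    runs just the standalone exact test on that literal 2x2 table.
    """
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}

    manifest: dict = {
        "package_version": __version__,
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": str(config_path),
        "config_digest": _digest(config_path),
        "inputs": {},
        "parameters": {},
        "stages": [],
        "warnings": [],
    }

    fisher_table = cfg.get("fisher_table")
    if fisher_table is not None:
        p = fisher_one_tail(fisher_table)
        pd.DataFrame(
            [{"a": fisher_table[0][0], "b": fisher_table[0][1],
              "c": fisher_table[1][0], "d": fisher_table[1][1],
              "one_tail_P": p, "one_tail_P_2dp": round(p, 2)}]
        ).to_csv(out / "fisher.tsv", sep="\t", index=False)
        manifest["stages"].append("fisher")
        manifest["parameters"]["fisher_table"] = fisher_table

    if "alignment" in cfg:
        aln_path = Path(cfg["alignment"])
        if not aln_path.exists():
            raise ConfigError(f"alignment file {aln_path} does not exist")
        aln = read_fasta_alignment(aln_path)
        manifest["inputs"]["alignment"] = {
            "path": str(aln_path), "sha256": _digest(aln_path)
        }

        model_name = cfg.get("model", "WAG")
        alpha = float(cfg.get("gamma_alpha", 1.1990))
        cats = int(cfg.get("gamma_cats", 2))
        threshold = float(cfg.get("threshold", 0.5))
        model = load_model(model_name)
        rates = discretize_gamma(alpha, cats)
        manifest["parameters"].update(
            {"model": model_name, "gamma_alpha": alpha, "gamma_cats": cats,
             "threshold": threshold}
        )

        tree_spec = cfg.get("tree", "nj")
        if tree_spec == "nj":
            tree = nj_tree(protein_distance(aln, model, rates))
            manifest["inputs"]["tree"] = {"source": "neighbor-joining start"}
        else:
            tree_path = Path(tree_spec)
            if not tree_path.exists():
                raise ConfigError(f"tree file {tree_path} does not exist")
            tree = read_newick(tree_path, offset=int(cfg.get("node_offset", 0)))
            manifest["inputs"]["tree"] = {
                "path": str(tree_path), "sha256": _digest(tree_path)
            }
        tree.bind(aln)

        if cfg.get("optimize_branch_lengths", True):
            tree, lnL, converged = optimize_branch_lengths(aln, tree, model, rates)
            if not converged:
                manifest["warnings"].append("branch-length optimization not converged")
        else:
            from .engine import site_log_likelihood

            _, lnL = site_log_likelihood(aln, tree, model, rates)
        (out / "tree_opt.nwk").write_text(to_newick(tree) + "\n")
        pd.DataFrame(
            [{"lnL": lnL, "model": model_name, "gamma_alpha": alpha,
              "gamma_cats": cats}]
        ).to_csv(out / "likelihood.tsv", sep="\t", index=False)
        manifest["stages"].append("liketree")

        anc = marginal_ancestral(aln, tree, model, rates)
        report = ancestral_sequence_report(anc, threshold)
        report.to_csv(out / "ancestors.tsv", sep="\t", index=False)
        write_fasta(
            [f"node_{i}" for i in anc.node_ids],
            [anc.masked_sequence(i, threshold) for i in anc.node_ids],
            out / "ancestors.fasta",
        )
        manifest["stages"].append("ancestors")

        focal_specs = cfg.get("focal", [])
        if isinstance(focal_specs, str):
            focal_specs = [focal_specs]
        if focal_specs:
            bdm_path = cfg.get("bdm_matrix")
            bdm = read_bdm_matrix(bdm_path) if bdm_path else derive_bdm()
            manifest["parameters"]["bdm_matrix"] = bdm.provenance
            rows, evidence = [], []
            for spec in focal_specs:
                focal = tree.parse_branch(str(spec))
                result = bdm_branch_test(anc, aln, tree, focal, bdm, threshold)
                rows.append(
                    {
                        "focal": f"{result.focal[0]}-{result.focal[1]}",
                        "neighbors": ";".join(f"{p}-{c}" for p, c in result.neighbors),
                        "BDM1": result.BDM1,
                        "R1": result.R1,
                        "BDM2": result.BDM2,
                        "R2": result.R2,
                        "one_tail_P": result.p_value if result.p_value is not None else "NA",
                        "note": result.note or "",
                    }
                )
                if result.note:
                    manifest["warnings"].append(f"{spec}: {result.note}")
                for reps in [result.focal_replacements] + result.neighbor_replacements:
                    for s in reps.sites:
                        evidence.append(
                            {
                                "focal": f"{result.focal[0]}-{result.focal[1]}",
                                "branch": f"{reps.branch[0]}-{reps.branch[1]}",
                                "site": s.site,
                                "parent_state": s.parent_state,
                                "parent_prob": s.parent_prob,
                                "child_state": s.child_state,
                                "child_prob": s.child_prob,
                                "bdm": s.bdm,
                            }
                        )
            pd.DataFrame(rows).to_csv(out / "bdm_test.tsv", sep="\t", index=False)
            pd.DataFrame(evidence).to_csv(
                out / "bdm_evidence.tsv", sep="\t", index=False
            )
            manifest["stages"].append("test")

        patterns = cfg.get("motifs", [])
        if isinstance(patterns, str):
            patterns = [patterns]
        if patterns:
            all_hits = []
            for pattern in patterns:
                all_hits.extend(scan_motif(aln, pattern))
            pd.DataFrame([h.__dict__ for h in all_hits]).to_csv(
                out / "motif_hits.tsv", sep="\t", index=False
            )
            clades = cfg.get("clades")
            if clades:
                clade_motif_table(tree, all_hits, clades).to_csv(
                    out / "clade_motifs.tsv", sep="\t", index=False
                )
            manifest["stages"].append("motifs")

        conserved = cfg.get("conserved_positions")
        if conserved:
            rep = conserved_column_report(
                aln, conserved["reference"], list(conserved["positions"])
            )
            rep.to_csv(out / "conserved_columns.tsv", sep="\t", index=False)
            conservation_counts(rep).to_csv(
                out / "conserved_summary.tsv", sep="\t", index=False
            )

    if not manifest["stages"]:
        raise ConfigError(
            "config requests no stages: provide 'fisher_table' and/or 'alignment'"
        )
    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
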