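"""End-to-end orchestration: sequences + landmarks -> report bundle.

``run_all`` drives every stage — distance matrix, group summaries, NJ
tree with bootstrap, AMOVA (full / one-clone-per-individual / most
distinct region dropped), pairwise Phi_ST, trait extraction, stepwise
discriminant with jackknifed classification, and the per-trait Mantel
screen — writing plain-text tables and a JSON manifest (config, derived
stage seeds, output hashes) for provenance.

One master seed drives everything: per-stage seeds are derived by
stable hashing of the stage name so stages stay uncorrelated while the
whole run is reproducible from one knob.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import Amova, clone_subset_amova, pairwise_phi_st
from .discriminant import anova_by_trait, forward_stepwise, jackknife_classify
from .mantel import genetic_region_matrix, screen_traits
from .njtree import bootstrap_support
from .seqdist import distance_matrix, group_distance_summary, read_labelled_fasta, slice_alignment
from .traits import LINEAR_TRAITS, specimen_summary, trait_table
from .landmarks import read_landmarks

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


@dataclass
class RunConfig:
    """Serializable configuration of one full analysis run."""

    fasta: str | None = None
    landmarks: str | None = None
    out_dir: str = "coraldelim_out"
    seed: int = 0
    target_species: str | None = None   # restrict AMOVA/Phi_ST; None = all
    gamma_a: float | None = 0.2
    amova_model: str = "k2p"            # or "weighted" (ts/tv/gap counts)
    ts_weight: float = 2.0
    tv_weight: float = 1.0
    gap_weight: float = 1.0
    n_perm: int = 10023
    mantel_perm: int = 9999
    bootstrap_reps: int = 1000
    f_to_enter: float = 4.0
    f_to_remove: float = 3.9
    its1_range: tuple | None = None     # (start, end) alignment columns, 0-based
    its2_range: tuple | None = None
    genetics_only: bool = False
    summary_boot: int = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("its1_range", "its2_range"):
            if known.get(k) is not None:
                known[k] = tuple(known[k])
        return cls(**known)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(path: Path, text: str):
    path.write_text(text)
    return path


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _summary_tsv(summary) -> str:
    df = summary.to_frame().round(6)
    se_w = pd.Series(summary.within_se).round(6)
    lines = ["# between/within mean distances (diagonal = within)"]
    lines.append(df.to_csv(sep="\t"))
    lines.append("# within SE")
    lines.append(se_w.to_csv(sep="\t", header=False))
    return "\n".join(lines)


def _amova_tsv(sections: dict) -> str:
    parts = []
    for title, res in sections.items():
        t = res.summary().round(4)
        parts.append(f"# {title}\tPhi_ST={res.phi_st:.4f}\tp={res.p_value:.5f}")
        parts.append(t.to_csv(sep="\t"))
    return "\n".join(parts)


def run_all(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "start"
    try:
        # ---- genetics -------------------------------------------------
        stage = "read sequences"
        records = read_labelled_fasta(cfg.fasta)
        regions = {r.seq_id: r.region for r in records}

        stage = "distance matrix"
        dm = distance_matrix(records, model="k2p", gamma_a=cfg.gamma_a)
        outputs["dm.phylip"] = _write(out / "dm.phylip", dm.to_phylip())

        stage = "group distance summary"
        slices = {"combined": records}
        if cfg.its1_range:
            slices["ITS-1"] = slice_alignment(records, *cfg.its1_range)
        if cfg.its2_range:
            slices["ITS-2"] = slice_alignment(records, *cfg.its2_range)
        summaries = {}
        parts = []
        for name, recs in slices.items():
            sdm = distance_matrix(recs, model="k2p", gamma_a=None)
            summ = group_distance_summary(
                sdm, regions, records=recs, n_boot=cfg.summary_boot,
                seed=stage_seed(cfg.seed, f"summary:{name}"),
            )
            summaries[name] = summ
            parts.append(f"## {name}\n" + _summary_tsv(summ))
        outputs["table3.tsv"] = _write(out / "table3.tsv", "\n".join(parts))

        stage = "NJ tree with bootstrap"
        tree = bootstrap_support(
            records, n_reps=cfg.bootstrap_reps,
            seed=stage_seed(cfg.seed, "bootstrap"), gamma_a=cfg.gamma_a,
        )
        outputs["tree.nwk"] = _write(out / "tree.nwk", str(tree))

        stage = "AMOVA"
        target = [
            r for r in records
            if cfg.target_species is None or r.species == cfg.target_species
        ]
        model_kw = dict(model=cfg.amova_model, gamma_a=cfg.gamma_a)
        if cfg.amova_model == "weighted":
            model_kw = dict(
                model="weighted", ts_weight=cfg.ts_weight,
                tv_weight=cfg.tv_weight, gap_weight=cfg.gap_weight,
            )

        def _amova_records(recs, seed_tag):
            return clone_subset_amova(
                recs, "all", n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, seed_tag), **model_kw,
            )

        res_all = _amova_records(target, "amova:all")
        res_subsets = clone_subset_amova(
            target, "one_per_individual", n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "amova:clones"), **model_kw,
        )
        # drop the region most distant from the rest (combined summary)
        summ = summaries["combined"]
        target_regions = sorted({r.region for r in target})
        btw = summ.to_frame().loc[target_regions, target_regions]
        mean_btw = (btw.sum(axis=1) - np.diag(btw)) / (len(btw) - 1)
        most_distinct = mean_btw.idxmax()
        res_drop = clone_subset_amova(
            target, f"drop_group:{most_distinct}", n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "amova:drop"), **model_kw,
        )
        sections = {"(A) All sequences included": res_all}
        for k, r in enumerate(res_subsets):
            sections[f"(B) Clone subset {k+1}"] = r
        sections[f"(C) Most distinct region ({most_distinct}) excluded"] = res_drop
        outputs["table4.tsv"] = _write(out / "table4.tsv", _amova_tsv(sections))

        stage = "pairwise Phi_ST"
        tdm = distance_matrix(target, **model_kw)
        tgroups = {r.seq_id: r.region for r in target}
        phi, pv = pairwise_phi_st(
            tdm, tgroups, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "phi_st")
        )
        # Phi_ST lower triangle, p upper triangle
        tbl5 = phi.round(4).copy()
        for i in range(len(tbl5)):
            for j in range(i + 1, len(tbl5)):
                tbl5.iloc[i, j] = round(pv.iloc[i, j], 5)
        outputs["table5.tsv"] = _write(
            out / "table5.tsv",
            "# lower triangle Phi_ST, upper triangle permutation p\n"
            + tbl5.to_csv(sep="\t"),
        )

        manifest_extra = {
            "most_distinct_region": most_distinct,
            "pct_among": res_all.pct_among,
            "phi_st": res_all.phi_st,
        }

        # ---- morphometrics -------------------------------------------
        if cfg.landmarks and not cfg.genetics_only:
            stage = "trait extraction"
            sets = read_landmarks(cfg.landmarks)
            traits = trait_table(sets)
            outputs["traits.csv"] = _write(
                out / "traits.csv", traits.to_csv(index_label="corallite_id")
            )

            stage = "per-trait ANOVA"
            tt = traits.drop(columns=["specimen_id", "species"])
            anova_tbl, _ = anova_by_trait(tt, "region")
            outputs["anova.tsv"] = _write(
                out / "anova.tsv", anova_tbl.round(6).to_csv(sep="\t")
            )

            stage = "stepwise discriminant"
            step = forward_stepwise(
                tt, "region", f_to_enter=cfg.f_to_enter, f_to_remove=cfg.f_to_remove
            )
            if step.final is None:
                raise RuntimeError("stepwise selection produced an empty model")
            cm = jackknife_classify(tt, "region", step.selected)
            tbl6 = cm.summary()
            eig = " ".join(f"{e:.3f}" for e in step.final.eigenvalues)
            outputs["table6.tsv"] = _write(
                out / "table6.tsv",
                f"# selected: {','.join(step.selected)}\t"
                f"Wilks_lambda={step.final.wilks_lambda:.4f}\teigenvalues: {eig}\n"
                + tbl6.to_csv(sep="\t"),
            )
            outputs["fig4_scores.csv"] = _write(
                out / "fig4_scores.csv", step.final.scores.round(6).to_csv()
            )
            manifest_extra.update(
                wilks_lambda=step.final.wilks_lambda,
                selected=step.selected,
                jackknife_total_pct=cm.total_pct_correct,
            )

            stage = "Mantel screen"
            spec_sum = specimen_summary(traits)
            morph_regions = sorted(spec_sum["region"].unique())
            usable = [r for r in morph_regions if r in summaries["combined"].groups]
            gm = genetic_region_matrix(summaries["combined"], usable)
            screen = screen_traits(
                gm, spec_sum[spec_sum["region"].isin(usable)], list(LINEAR_TRAITS),
                n_perm=cfg.mantel_perm, seed=stage_seed(cfg.seed, "mantel"),
            )
            outputs["table7.tsv"] = _write(
                out / "table7.tsv", screen.round(6).to_csv(sep="\t", index=False)
            )
            # raw pair scatter data for the regression figure
            iu, ju = np.triu_indices(len(gm), k=1)
            pairs = pd.DataFrame(
                {
                    "region_a": np.asarray(gm.labels)[iu],
                    "region_b": np.asarray(gm.labels)[ju],
                    "genetic": gm.values[iu, ju],
                }
            )
            outputs["fig5_pairs.csv"] = _write(
                out / "fig5_pairs.csv", pairs.round(6).to_csv(index=False)
            )
            manifest_extra["top_trait"] = (
                screen.iloc[0]["trait"] if len(screen) else None
            )
    except Exception as e:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {e} "
            f"(partial outputs kept in {out})"
        ) from e

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {
            s: stage_seed(cfg.seed, s)
            for s in ("bootstrap", "amova:all", "amova:clones", "amova:drop",
                       "phi_st", "mantel")
        },
        "outputs": {name: _sha(p) for name, p in sorted(outputs.items())},
        **manifest_extra,
    }
    _write(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
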