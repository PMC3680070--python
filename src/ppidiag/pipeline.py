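"""End-to-end orchestration: corpora + predictions -> full report bundle.

``run_report`` drives the whole instance-level analysis and writes every
table twice — a human-readable TSV and a JSON twin with identical numbers —
plus a manifest recording tool version, configuration hash, seeds and input
digests, so a bundle is reproducible byte for byte from its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_matrix, cluster, to_newick
from .difficulty import (
    combine_settings,
    compute_success_levels,
    extract_difficulty_sets,
    overlap_chi2,
)
from .difficulty import crosstab_cv_cl
from .evaluation import (
    ensemble_eval,
    majority_vote,
    positive_rate,
    relabel_and_rescore,
    stratum_report,
)
from .feature_analysis import EvalProtocol, evaluate_difficulty_model, rank_features
from .features import Lexicons, feature_table
from .io import (
    parse_unified_corpus,
    read_flip_list,
    read_predictions,
    write_folds,
    write_predictions,
    write_unified_corpus,
)
from .model import Corpus, PredictionSet, ValidationError, merge_gold
from .simulate import generate_benchmark_suite, random_folds

__all__ = ["RunConfig", "run_report", "simulate_to_files", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and knobs of a full report run."""

    corpus_paths: list[str] = field(default_factory=list)
    predictions_cv: str | None = None
    predictions_cl: str | None = None
    folds_path: str | None = None
    flip_list: str | None = None
    fraction: float = 0.10
    difficult_rule: str = "closest"
    easy_rule: str = "at_least"
    linkage: str = "complete"
    agreement_setting: str = "CV"
    committee: list[str] = field(default_factory=lambda: ["APG", "SL", "kBSPS"])
    tie_rule: str = "error"
    top_k_features: int = 10
    seed: int = 0
    out_dir: str = "report"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_twin(df: pd.DataFrame, out: Path, name: str) -> None:
    df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    with open(out / f"{name}.json", "w") as fh:
        json.dump(
            json.loads(df.to_json(orient="records")), fh, indent=1, sort_keys=True
        )


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _success_frame(tables: dict[str, Any], gold: dict[str, bool]) -> pd.DataFrame:
    rows = []
    for name, table in tables.items():
        hist = table.histogram()
        pos = np.zeros_like(hist)
        for pid, s in table.levels.items():
            if gold[pid]:
                pos[s] += 1
        for level in range(len(hist)):
            rows.append(
                {
                    "corpus": name,
                    "level": level,
                    "total": int(hist[level]),
                    "positive": int(pos[level]),
                    "negative": int(hist[level] - pos[level]),
                }
            )
    return pd.DataFrame(rows)


def run_report(
    config: RunConfig,
    corpora: list[Corpus] | None = None,
    predictions: dict[str, PredictionSet] | None = None,
) -> dict[str, Any]:
    """Run the full analysis and write the report bundle.

    Inputs may be passed in memory (``corpora`` + ``predictions`` with keys
    CV/CL) or loaded from the paths in ``config``.  Returns a summary dict
    with the manifest and key in-memory results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_digests = {}

    stage = "load"
    try:
        if corpora is None:
            corpora = [parse_unified_corpus(p) for p in config.corpus_paths]
            input_digests.update(
                {str(p): _file_digest(p) for p in config.corpus_paths}
            )
        if predictions is None:
            predictions = {}
            if config.predictions_cv:
                predictions["CV"] = read_predictions(config.predictions_cv, "CV")
                input_digests[str(config.predictions_cv)] = _file_digest(
                    config.predictions_cv
                )
            if config.predictions_cl:
                predictions["CL"] = read_predictions(config.predictions_cl, "CL")
                input_digests[str(config.predictions_cl)] = _file_digest(
                    config.predictions_cl
                )
        if not corpora or "CV" not in predictions or "CL" not in predictions:
            raise ValidationError("need corpora plus CV and CL predictions")
        gold = merge_gold(corpora)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    results: dict[str, Any] = {}

    def run_stage(name: str, fn):
        nonlocal stage
        stage = name
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    # --- success levels and histograms (per corpus, per setting)
    def _success():
        tables = {}
        for setting in ("CV", "CL"):
            pset = predictions[setting]
            per_corpus = {
                c.name: compute_success_levels(c, pset) for c in corpora
            }
            tables[setting] = per_corpus
            _write_twin(
                _success_frame(per_corpus, gold),
                out,
                f"success_histogram_{setting.lower()}",
            )
        return tables

    success = run_stage("success-levels", _success)

    # --- difficulty sets, combination, overlap tests
    def _difficulty():
        sets = {
            setting: {
                name: extract_difficulty_sets(
                    table,
                    config.fraction,
                    config.difficult_rule,
                    config.easy_rule,
                )
                for name, table in success[setting].items()
            }
            for setting in ("CV", "CL")
        }
        combined = {}
        rows = []
        for c in corpora:
            cv, cl = sets["CV"][c.name], sets["CL"][c.name]
            cgold = c.gold()
            comb = combine_settings(cv, cl, cgold)
            combined[c.name] = comb
            universe = len(cgold)
            for cls, a, b in (
                ("D", cv.difficult, cl.difficult),
                ("E", cv.easy, cl.easy),
            ):
                for sub, filt in (
                    (cls, None),
                    (("P" + cls), True),
                    (("N" + cls), False),
                ):
                    aa = a if filt is None else {p for p in a if cgold[p] is filt}
                    bb = b if filt is None else {p for p in b if cgold[p] is filt}
                    try:
                        test = overlap_chi2(aa, bb, universe)
                        expected, p_value = test.expected, test.p_value
                        significant = test.significant
                    except ValidationError:
                        expected = len(aa) * len(bb) / universe
                        p_value, significant = float("nan"), False
                    rows.append(
                        {
                            "corpus": c.name,
                            "class": sub,
                            "cv_size": len(aa),
                            "cl_size": len(bb),
                            "overlap": len(aa & bb),
                            "expected": round(expected, 1),
                            "p_value": p_value,
                            "significant": significant,
                            "rule_flags": "; ".join(
                                sorted(
                                    set(cv.rule_disagreement) | set(cl.rule_disagreement)
                                )
                            ),
                        }
                    )
        _write_twin(pd.DataFrame(rows), out, "difficulty_overlap")
        return sets, combined

    sets, combined = run_stage("difficulty", _difficulty)

    # --- stratum reports on the pooled subclasses (Tables 4-11 shape)
    def _strata():
        frames = []
        strata = {
            sub: set().union(
                *(comb.members(sub) for comb in combined.values())
            )
            for sub in ("ND", "PD", "NE", "PE")
        }
        results["stratum_sizes"] = {k: len(v) for k, v in strata.items()}
        for setting in ("CV", "CL"):
            pset = predictions[setting]
            rates = {
                cid: positive_rate(cid, pset).r for cid in pset.roster
            }
            for sub, stratum in strata.items():
                if not stratum:
                    continue
                polarity = "positive" if sub.startswith("P") else "negative"
                for cid in pset.roster:
                    rep = stratum_report(
                        cid, pset, gold, stratum, polarity,
                        stratum_name=sub, r=rates[cid],
                    )
                    frames.append(
                        {
                            "setting": setting,
                            "stratum": sub,
                            "size": rep.stratum_size,
                            "classifier": cid,
                            "r_population": "pooled-per-setting",
                            **rep.rounded(),
                        }
                    )
        _write_twin(pd.DataFrame(frames), out, "stratum_reports")
        return strata

    strata = run_stage("strata", _strata)

    # --- CV/CL success-level crosstab (Figure-3 shape)
    def _crosstab():
        pooled_cv = {
            pid: s for t in success["CV"].values() for pid, s in t.levels.items()
        }
        pooled_cl = {
            pid: s for t in success["CL"].values() for pid, s in t.levels.items()
        }
        roster_cv = predictions["CV"].roster
        roster_cl = predictions["CL"].roster
        from .difficulty import SuccessTable

        mat = crosstab_cv_cl(
            SuccessTable("CV", roster_cv, pooled_cv),
            SuccessTable("CL", roster_cl, pooled_cl),
        )
        df = pd.DataFrame(
            mat,
            index=[f"cv_{i}" for i in range(mat.shape[0])],
            columns=[f"cl_{j}" for j in range(mat.shape[1])],
        ).reset_index(names="level")
        _write_twin(df, out, "success_crosstab")
        return mat

    run_stage("crosstab", _crosstab)

    # --- agreement clustering (Figure-8 shape)
    def _agreement():
        pset = predictions[config.agreement_setting.upper()]
        mat = agreement_matrix(pset)
        mat.reset_index(names="classifier").to_csv(
            out / "agreement_matrix.tsv", sep="\t", index=False
        )
        tree = cluster(mat, linkage=config.linkage)
        newick = to_newick(tree)
        (out / "agreement_dendrogram.nwk").write_text(newick + "\n")
        with open(out / "agreement_matrix.json", "w") as fh:
            json.dump(
                {
                    "setting": config.agreement_setting.upper(),
                    "linkage": config.linkage,
                    "matrix": mat.round(6).to_dict(),
                    "newick": newick,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        return mat, newick

    run_stage("agreement", _agreement)

    # --- features + information gain (Tables 15-16 shape)
    def _features():
        lex = Lexicons()
        tables = [feature_table(c, lex) for c in corpora]
        ft = pd.concat(tables)
        ft.reset_index(names="pair_id").to_csv(
            out / "feature_table.tsv", sep="\t", index=False
        )
        with open(out / "feature_registry.json", "w") as fh:
            json.dump(sorted(ft.columns), fh, indent=1)
        ig_rows = []
        for cls in ("D", "E"):
            members = set().union(
                *(comb.members(cls) for comb in combined.values())
            )
            indicator = {pid: pid in members for pid in ft.index}
            for e in rank_features(ft, indicator, k=config.top_k_features):
                ig_rows.append(
                    {
                        "class": cls,
                        "rank": e.rank,
                        "feature": e.feature,
                        "sign": e.sign,
                        "IG": round(e.ig, 4),
                    }
                )
        _write_twin(pd.DataFrame(ig_rows), out, "information_gain")
        return ft

    ft = run_stage("features", _features)

    # --- difficulty-class prediction (Table-12 shape)
    def _difficulty_model():
        classes = {}
        for comb in combined.values():
            classes.update(comb.classes)
        report = evaluate_difficulty_model(
            ft, classes, EvalProtocol(mode="cv", seed=config.seed)
        )
        frame = report.to_frame()
        frame.insert(0, "protocol", "document-level 10-fold CV, pooled confusion")
        _write_twin(frame, out, "difficulty_model")
        return report

    run_stage("difficulty-model", _difficulty_model)

    # --- majority-vote ensemble (Table-17 shape)
    def _ensemble():
        pset = predictions["CV"]
        committee = [c for c in config.committee if c in pset.roster]
        if len(committee) >= 2:
            ens = majority_vote(pset, committee, tie_rule=config.tie_rule)
            frames = [ensemble_eval(ens, corpora)]
            for cid in committee:
                single = majority_vote(pset, [cid], ensemble_id=cid)
                frames.append(ensemble_eval(single, corpora))
            _write_twin(pd.concat(frames, ignore_index=True), out, "ensemble")

    run_stage("ensemble", _ensemble)

    # --- optional relabel-and-rescore
    def _relabel():
        if not config.flip_list:
            return
        from .model import normalize_pair_id

        flips = [normalize_pair_id(pid) for pid in read_flip_list(config.flip_list)]
        known = [pid for pid in flips if pid in gold]
        rows = []
        pset = predictions["CV"]
        for cid in pset.roster:
            rep = relabel_and_rescore(pset.column(cid), gold, known)
            rows.append(
                {
                    "classifier": cid,
                    "n_flipped": rep["n_flipped"],
                    "changed_fraction": round(rep["changed_fraction"], 4),
                    "P_before": round(rep["before_prf"].P, 1),
                    "R_before": round(rep["before_prf"].R, 1),
                    "F_before": round(rep["before_prf"].F, 1),
                    "P_after": round(rep["after_prf"].P, 1),
                    "R_after": round(rep["after_prf"].R, 1),
                    "F_after": round(rep["after_prf"].F, 1),
                }
            )
        _write_twin(pd.DataFrame(rows), out, "relabel_rescore")

    run_stage("relabel", _relabel)

    manifest = {
        "tool": "ppidiag",
        "version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "input_digests": input_digests,
        "corpora": {c.name: len(list(c.pair_ids())) for c in corpora},
        "artifacts": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    results["combined"] = combined
    results["strata"] = strata
    return results


def simulate_to_files(
    out_dir: str | Path, seed: int = 0, size_factor: float = 0.1
) -> dict[str, str]:
    """Generate the five-corpus synthetic benchmark and write it in the
    formats ``run_report`` consumes unchanged."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suite = generate_benchmark_suite(seed, size_factor=size_factor)
    paths: dict[str, str] = {}
    fold_map = {}
    for corpus in suite.corpora:
        path = out / f"{corpus.name}.xml"
        write_unified_corpus(corpus, path)
        paths[corpus.name] = str(path)
        fold_map.update(
            random_folds(corpus, seed=seed).mapping
        )
    from .model import FoldAssignment

    write_predictions(suite.cv, out / "predictions_cv.tsv")
    write_predictions(suite.cl, out / "predictions_cl.tsv")
    write_folds(FoldAssignment(mapping=fold_map), out / "folds.tsv")
    paths["predictions_cv"] = str(out / "predictions_cv.tsv")
    paths["predictions_cl"] = str(out / "predictions_cl.tsv")
    paths["folds"] = str(out / "folds.tsv")
    return paths
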