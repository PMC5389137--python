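"""End-to-end orchestration: validate, merge, superimpose, analyse, classify.

The stages mirror the analysis workflow: dataset validation, dorsal/
ventral view merging, generalized Procrustes superimposition with object
symmetry on the reference sample, measurement-error ANOVA, replicate
averaging, form-space PCA with unknown projection, size permutation
tests, balanced-resampling QDA classification, and the cranial-index
negative control.  Unknowns never influence the reference frame: they
are fitted to the frozen consensus and projected onto the reference
eigenvectors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices as idx
from .classify import ClassificationReport, DiscriminationSummary, ResampledQDA
from .formspace import (
    FormSpacePCA,
    PermutationTestResult,
    allometry_correlations,
    anderson_retained_pcs,
    build_form_space,
    form_matrix,
    permutation_test,
)
from .io import Dataset, LandmarkConfiguration, merge_views, validate_dataset, write_tps
from .procrustes import (
    AnovaTable,
    GeneralizedProcrustes,
    average_replicates,
    centroid_size,
    procrustes_anova,
)
from .simulate import DEFAULT_MEASUREMENTS, MATCHING_LANDMARKS

WOLF_GROUPS = {"arctic_wolf", "eurasian_wolf"}


@dataclass
class RunConfig:
    n_iter: int = 1000
    posterior_threshold: float = 0.90
    call_fraction: float = 0.90
    alpha_anderson: float = 0.05
    priors: tuple[float, float] = (0.5, 0.5)
    n_perm: int = 1000
    seed: int = 0
    matching_landmarks: list[str] = field(default_factory=lambda: list(MATCHING_LANDMARKS))
    measurements: dict = field(default_factory=lambda: dict(DEFAULT_MEASUREMENTS))
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100

    def validate(self) -> None:
        if not 0 < self.posterior_threshold < 1:
            raise ValueError("posterior_threshold must be in (0, 1)")
        if not 0 < self.call_fraction < 1:
            raise ValueError("call_fraction must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not np.isclose(sum(self.priors), 1.0):
            raise ValueError("priors must sum to 1")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    gpa: GeneralizedProcrustes
    anova: AnovaTable
    ref_ids: list[str]
    ref_groups: list[str]            # dog / arctic_wolf / eurasian_wolf
    ref_shapes: np.ndarray           # averaged symmetric components
    ref_cs: np.ndarray               # mm
    unknown_ids: list[str]
    unknown_shapes: np.ndarray
    unknown_cs: np.ndarray
    space: FormSpacePCA
    ref_scores: np.ndarray
    unknown_scores: np.ndarray
    anderson_k: int
    allometry_r: np.ndarray
    size_mean_test: PermutationTestResult
    size_variance_test: PermutationTestResult
    report: ClassificationReport
    summary: DiscriminationSummary
    index_table: pd.DataFrame
    index_scores_ref: pd.DataFrame
    index_scores_proj: pd.DataFrame | None
    bivariate_hulls: dict[str, np.ndarray]

    @property
    def two_group_labels(self) -> np.ndarray:
        return np.array(
            ["wolf" if g in WOLF_GROUPS else g for g in self.ref_groups]
        )


def _combined_replicates(dataset: Dataset, matching: list[str]) -> dict[str, list[LandmarkConfiguration]]:
    """Combined configuration per specimen per replicate, merging views if needed."""
    out: dict[str, list[LandmarkConfiguration]] = {}
    for sp in dataset.specimens:
        combined = {c.replicate: c for c in sp.configurations if c.view == "combined"}
        if not combined:
            by_rep: dict[int, dict[str, LandmarkConfiguration]] = {}
            for c in sp.configurations:
                by_rep.setdefault(c.replicate, {})[c.view] = c
            for rep, views in sorted(by_rep.items()):
                if "dorsal" not in views or "ventral" not in views:
                    raise ValueError(
                        f"specimen {sp.id} replicate {rep}: missing a view"
                    )
                combined[rep] = merge_views(views["dorsal"], views["ventral"], matching)
        out[sp.id] = [combined[r] for r in sorted(combined)]
    return out


def run_pipeline(dataset: Dataset, config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    config.validate()

    report = validate_dataset(dataset)
    if report.fatal:
        msgs = "; ".join(f.message for f in report.findings if f.severity == "fatal")
        raise ValueError(f"validation failed: {msgs}")

    combined = _combined_replicates(dataset, config.matching_landmarks)
    ref = dataset.references()
    unknowns = dataset.projected()
    labels = combined[ref[0].id][0].labels

    ref_cfgs: list[LandmarkConfiguration] = []
    ref_rep_ids: list[str] = []
    for sp in ref:
        for c in combined[sp.id]:
            ref_cfgs.append(c.reordered(labels))
            ref_rep_ids.append(sp.id)

    gpa = GeneralizedProcrustes(
        symmetry=dataset.symmetry,
        labels=labels,
        tol=config.gpa_tol,
        max_iter=config.gpa_max_iter,
    )
    gpa.fit(ref_cfgs)

    n_reps = max(len(combined[sp.id]) for sp in ref)
    anova = (
        procrustes_anova(gpa.aligned_, ref_rep_ids)
        if n_reps >= 2
        else AnovaTable(effects=[], goodall_f=np.nan, p=np.nan)
    )

    ref_ids, ref_shapes, ref_cs = average_replicates(
        gpa.symmetric_, gpa.centroid_sizes_, ref_rep_ids
    )
    group_of = {sp.id: sp.group for sp in dataset.specimens}
    ref_groups = [group_of[i] for i in ref_ids]

    unknown_ids: list[str] = []
    unknown_shapes_list = []
    unknown_cs_list = []
    for sp in unknowns:
        cfgs = [c.reordered(labels) for c in combined[sp.id]]
        sym_shapes = gpa.transform(cfgs)
        unknown_ids.append(sp.id)
        unknown_shapes_list.append(sym_shapes.mean(axis=0))
        unknown_cs_list.append(np.mean([centroid_size(c.coords) for c in cfgs]))
    unknown_shapes = (
        np.stack(unknown_shapes_list) if unknown_shapes_list else np.empty((0, len(labels), 3))
    )
    unknown_cs = np.asarray(unknown_cs_list)

    # form space on references only
    space = build_form_space(ref_shapes, ref_cs)
    ref_scores = space.scores_
    unknown_scores = (
        space.transform(form_matrix(unknown_shapes, unknown_cs))
        if len(unknown_ids)
        else np.empty((0, ref_scores.shape[1]))
    )
    # exact dimension of the symmetric form space: 3 coords per landmark
    # pair + 2 per midline point, minus 2 in-plane translations, 1 rotation
    # and the scale, plus the lnCS column; eigenvalues past it are
    # alignment leakage, not variation
    form_rank = (
        3 * len(dataset.symmetry.pairs)
        + 2 * len(dataset.symmetry.midline)
        - 4
        + 1
    )
    anderson_k = anderson_retained_pcs(
        space.explained_variance_[:form_rank], n=len(ref_ids),
        alpha=config.alpha_anderson,
    )
    lncs = np.log(ref_cs)
    allometry_r = allometry_correlations(space, lncs)

    two_group = np.array(["wolf" if g in WOLF_GROUPS else g for g in ref_groups])
    size_mean_test = permutation_test(
        lncs, two_group, "mean_difference", config.n_perm, seed=config.seed
    )
    wolves_mask = two_group == "wolf"
    wolf_sub = np.array(ref_groups, dtype=object)[wolves_mask]
    wolf_lncs = lncs[wolves_mask]
    centered = wolf_lncs.copy()
    for g in np.unique(wolf_sub):
        centered[wolf_sub == g] -= wolf_lncs[wolf_sub == g].mean()
    size_variance_test = permutation_test(
        centered, wolf_sub.astype(str), "variance_difference", config.n_perm,
        seed=config.seed + 1,
    )

    ref_forms = form_matrix(ref_shapes, ref_cs)
    model = ResampledQDA(
        n_iter=config.n_iter,
        threshold=config.posterior_threshold,
        call_fraction=config.call_fraction,
        priors=np.asarray(config.priors),
        alpha=config.alpha_anderson,
        form_rank=form_rank,
        random_state=config.seed,
    )
    model.fit(ref_forms, two_group)
    if len(unknown_ids):
        cls_report, summary = model.predict(
            form_matrix(unknown_shapes, unknown_cs), ids=unknown_ids
        )
    else:
        cls_report, summary = model.predict(
            ref_forms[:1], ids=["__none__"]
        )
        cls_report.calls = []

    # cranial indices on original-scale merged configurations
    scheme = idx.MeasurementScheme(config.measurements)
    all_cfgs = [c for sid in combined for c in combined[sid]]
    groups = {sp.id: sp.group for sp in dataset.specimens}
    table = idx.compute_indices(all_cfgs, groups, scheme)
    ref_table = table.loc[[i for i in table.index if groups[i] != "unknown"]]
    proj_table = table.loc[[i for i in table.index if groups[i] == "unknown"]]
    scores_ref, scores_proj, _ = idx.index_pca_project(
        ref_table, proj_table if len(proj_table) else None
    )
    _, hulls = idx.bivariate_export(
        table, "log10_greatest_palate_width", "log10_total_skull_length"
    )

    return PipelineResult(
        config=config,
        gpa=gpa,
        anova=anova,
        ref_ids=ref_ids,
        ref_groups=ref_groups,
        ref_shapes=ref_shapes,
        ref_cs=ref_cs,
        unknown_ids=unknown_ids,
        unknown_shapes=unknown_shapes,
        unknown_cs=unknown_cs,
        space=space,
        ref_scores=ref_scores,
        unknown_scores=unknown_scores,
        anderson_k=anderson_k,
        allometry_r=allometry_r,
        size_mean_test=size_mean_test,
        size_variance_test=size_variance_test,
        report=cls_report,
        summary=summary,
        index_table=table,
        index_scores_ref=scores_ref,
        index_scores_proj=scores_proj,
        bivariate_hulls=hulls,
    )


# ---------------------------------------------------------------------------
# Exports

def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the analysis bundle as plain-text tables (stamped with seed/config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# seed={result.config.seed} config={result.config.digest()}\n"

    def _frame(df: pd.DataFrame, name: str) -> None:
        with open(out / name, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t")

    scores = pd.DataFrame(
        result.ref_scores[:, : min(10, result.ref_scores.shape[1])],
        index=pd.Index(result.ref_ids, name="specimen"),
        columns=[f"PC{i + 1}" for i in range(min(10, result.ref_scores.shape[1]))],
    )
    scores["group"] = result.ref_groups
    scores["lncs"] = np.log(result.ref_cs)
    _frame(scores, "formspace_scores.tsv")

    lam = result.space.explained_variance_
    _frame(
        pd.DataFrame(
            {"eigenvalue": lam, "variance_pct": 100 * lam / lam.sum()},
            index=pd.Index(range(1, len(lam) + 1), name="PC"),
        ),
        "formspace_eigenvalues.tsv",
    )
    _frame(result.report.to_frame().set_index("specimen"), "classification_table.tsv")
    _frame(result.index_table, "cranial_indices.tsv")

    hull_rows = []
    for g, verts in result.bivariate_hulls.items():
        for x, y in np.atleast_2d(verts):
            hull_rows.append({"group": g, "x": x, "y": y})
    _frame(pd.DataFrame(hull_rows).set_index("group"), "bivariate_hulls.tsv")

    with open(out / "anova.txt", "w") as fh:
        fh.write(stamp)
        fh.write(str(result.anova) + "\n")

    from .io import LandmarkConfiguration  # consensus export

    write_tps(
        [
            LandmarkConfiguration(
                "consensus", "combined", 1,
                [f"L{i + 1}" for i in range(len(result.gpa.consensus_))],
                result.gpa.consensus_,
            )
        ],
        out / "consensus.tps",
    )

    log = {
        "seed": result.config.seed,
        "config_digest": result.config.digest(),
        "config": asdict(result.config),
        "gpa_iterations": result.gpa.n_iter_,
        "anderson_retained_pcs": result.anderson_k,
        "allometry_r": result.allometry_r.tolist(),
        "size_mean_test_p": result.size_mean_test.p,
        "size_variance_test_p": result.size_variance_test.p,
        "goodall_f": result.anova.goodall_f,
        "percent_correct": result.summary.percent_correct,
        "tau": result.summary.tau,
        "wilks_lambda": result.summary.wilks_lambda,
        "box_m": list(result.summary.box_m),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
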