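"""End-to-end camouflage analysis: from specimens, habitat and tree to report.

:class:`CamouflageAnalysis` is the top-level model object.  Built from a
specimen table (fur colours), per-specimen habitat colours and a phylogeny,
``fit()`` runs the full chain — repeatability, species ANOVA, phylogenetic
eigenvector extraction and selection, PSR curves, global and per-species
PLSR with bootstrap inference, residual correlations and a variance
partition — and returns an :class:`AnalysisResults` bundle of tables that
can be written to disk and reproduced exactly from a config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from crypsis import phylo_eigen as pe
from crypsis import plsr as pls
from crypsis import stats_core as sc
from crypsis.colorimetry import total_reflectance

__all__ = [
    "RunConfig",
    "CamouflageAnalysis",
    "AnalysisResults",
    "variance_partition",
    "run_full",
    "sensitivity_rerun",
]

TRAITS = ("red", "green", "blue", "L")


@dataclass
class RunConfig:
    """Tunable thresholds and sizes of a full analysis run.

    moran_threshold: residual Moran's I below which eigenvector selection
    stops (default 0.06); q2_threshold: Q² component-retention rule;
    bootstrap_B: bootstrap replicates; per_species_min_n: minimum specimen
    count for a separate per-species model (default 21, i.e. n > 20).
    """

    tree: str | None = None  # newick path
    specimens: str | None = None  # CSV path
    images_manifest: str | None = None  # CSV of photo patches (fur colours)
    habitat_raster: str | None = None  # TIFF+sidecar (habitat colours)
    moran_threshold: float = 0.06
    moran_weights: str = "inverse"
    q2_threshold: float = pls.Q2_THRESHOLD
    cv_folds: int = 10
    bootstrap_B: int = 1000
    per_species_min_n: int = 21
    single_response_models: bool = True
    buffer_radius: float = 1000.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.moran_threshold <= 0 or self.q2_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be at least 100")
        if self.per_species_min_n < 2:
            raise ValueError("per_species_min_n must be at least 2")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def variance_partition(
    results: pls.PLSResults,
    groups: list[str],
) -> dict[str, float]:
    """Split the PLSR-explained variance across predictor blocks.

    Each predictor's importance share (variance-weighted squared weight) is
    summed within its block — habitat colours, geography (latitude and
    longitude), collection/field origin, phylogenetic eigenvectors — and
    multiplied by the model's total explained percentage, so the block
    percentages sum to the explained variance.
    """
    if results.fit_ is None:
        return {g: 0.0 for g in set(groups)}
    shares, _ = results.importance()
    if len(groups) != shares.size:
        raise ValueError("group labels do not match predictor count")
    known = {"habitat", "geography", "origin", "phylogeny"}
    unknown = set(groups) - known
    if unknown:
        raise ValueError(f"unknown predictor blocks: {sorted(unknown)}")
    total = results.explained_variance
    out = {g: 0.0 for g in known}
    for g, s in zip(groups, shares):
        out[g] += float(s) * total
    return out


class CamouflageAnalysis:
    """Phenotype-habitat colour-matching model over a full study dataset.

    Parameters
    ----------
    specimens : table with columns id, species, latitude, longitude,
        origin (field/museum), collection, fur_red/green/blue and
        habitat_red/green/blue (fur_L / habitat_L are recomputed via BT.601
        when absent).  Repeated fur measurements (columns
        ``fur_<c>_repeat``) and paired habitat periods
        (``habitat_<c>_p1`` / ``_p2``) enable the repeatability section.
    tree : the species phylogeny (``PhyloTree`` or newick string);
        every species in the table must be a tip.
    """

    def __init__(
        self,
        specimens: pd.DataFrame,
        tree: pe.PhyloTree | str,
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        self.tree = tree if isinstance(tree, pe.PhyloTree) else pe.parse_newick(tree)
        self.specimens = specimens.reset_index(drop=True).copy()
        missing = sorted(set(self.specimens["species"]) - set(self.tree.taxa))
        if missing:
            raise ValueError(f"species missing from tree: {missing}")
        for kind in ("fur", "habitat"):
            if f"{kind}_L" not in self.specimens.columns:
                self.specimens[f"{kind}_L"] = total_reflectance(
                    self.specimens[f"{kind}_red"],
                    self.specimens[f"{kind}_green"],
                    self.specimens[f"{kind}_blue"],
                )

    @classmethod
    def from_config(cls, config: RunConfig) -> "CamouflageAnalysis":
        """Build from file paths: fur colours either precomputed in the
        specimen CSV or extracted from a photo-patch manifest; habitat
        colours either precomputed or buffer-extracted from a raster."""
        if not config.tree or not config.specimens:
            raise ValueError("config must give tree and specimens paths")
        tree = pe.parse_newick(Path(config.tree).read_text())
        specimens = pd.read_csv(config.specimens)
        if config.images_manifest:
            from crypsis.colorimetry import extract_specimen_colours

            colours = extract_specimen_colours(pd.read_csv(config.images_manifest))
            colours = colours.rename(
                columns={t: f"fur_{t}" for t in ("red", "green", "blue", "L")}
            )
            specimens = specimens.drop(
                columns=[c for c in specimens.columns if c.startswith("fur_")],
                errors="ignore",
            ).merge(colours, on="id", validate="one_to_one")
        if config.habitat_raster:
            from crypsis.habitat import HabitatRaster, SamplePoint, buffer_mean

            raster = HabitatRaster.read(config.habitat_raster)
            geographic = raster.transform.geographic
            cols = {f"habitat_{t}": [] for t in ("red", "green", "blue", "L")}
            for _, row in specimens.iterrows():
                if geographic:
                    pt = SamplePoint(str(row["id"]), row["longitude"], row["latitude"])
                else:
                    pt = SamplePoint(str(row["id"]), row["x"], row["y"])
                c = buffer_mean(raster, pt, config.buffer_radius)
                cols["habitat_red"].append(c.red)
                cols["habitat_green"].append(c.green)
                cols["habitat_blue"].append(c.blue)
                cols["habitat_L"].append(c.total_reflectance)
            for k, v in cols.items():
                specimens[k] = v
        return cls(specimens, tree, config)

    # ---------------------------------------------------------------- stages

    def _repeatability(self) -> pd.DataFrame:
        rows = []
        df = self.specimens
        for kind, suffixes in (
            ("fur", ("", "_repeat")),
            ("habitat", ("_p1", "_p2")),
        ):
            for trait in TRAITS:
                a, b = (f"{kind}_{trait}{s}" for s in suffixes)
                if a in df.columns and b in df.columns:
                    res = sc.icc(df[[a, b]].to_numpy(float))
                    rows.append(
                        {
                            "measure": kind,
                            "trait": trait,
                            "tau": res.tau,
                            "F": res.F,
                            "df_between": res.df_between,
                            "df_within": res.df_within,
                            "p": res.p,
                        }
                    )
        return pd.DataFrame(rows)

    def _anova(self) -> pd.DataFrame:
        df = self.specimens
        rows = []
        for kind in ("fur", "habitat"):
            covs = (
                df[["origin", "collection"]]
                if kind == "fur"
                else None
            )
            for trait in TRAITS:
                res = sc.anova_species(
                    df[f"{kind}_{trait}"].to_numpy(float), df["species"], covs
                )
                rows.append(
                    {
                        "measure": kind,
                        "trait": trait,
                        "F": res.F,
                        "df_effect": res.df_effect,
                        "df_resid": res.df_resid,
                        "p": res.p,
                    }
                )
        return pd.DataFrame(rows)

    def _species_means(self) -> pd.DataFrame:
        """Per-species mean fur colour, origin-adjusted then log-standardized.

        The field/museum brightness offset is removed by residualizing each
        trait on the origin factor before averaging (the per-species display
        convention: values 'accounted for variation between field/collections
        specimens')."""
        df = self.specimens
        origin_dummies = pd.get_dummies(df["origin"], drop_first=True).to_numpy(float)
        out = {}
        for trait in TRAITS:
            y = np.log10(df[f"fur_{trait}"].to_numpy(float))
            resid = sc.residualize(y, origin_dummies) + y.mean()
            out[trait] = pd.Series(resid).groupby(df["species"]).mean()
        means = pd.DataFrame(out)
        return means.loc[[t for t in self.tree.taxa if t in means.index]]

    def _phylogenetics(self, tree: pe.PhyloTree):
        D = pe.patristic_distances(tree)
        basis = pe.pvr_eigenvectors(D)
        W = pe.phylo_weight_matrix(D, self.config.moran_weights)
        means = self._species_means()
        if list(means.index) != list(tree.taxa):
            means = means.loc[list(tree.taxa)]
        psr_rows, sel_rows, selected_union = [], [], []
        for trait in TRAITS:
            vals = means[trait].to_numpy(float)
            curve = pe.psr_curve(vals, basis)
            psr_rows.append(
                {
                    "trait": trait,
                    "mean_deviation": curve.mean_deviation,
                    "area_deviation": curve.area_deviation,
                }
            )
            sel, met = pe.select_eigenvectors(
                vals, basis, W, self.config.moran_threshold
            )
            sel_rows.append(
                {
                    "trait": trait,
                    "selected": ",".join(f"EV{j + 1}" for j in sel),
                    "threshold_met": met,
                    "moran_I_raw": pe.morans_i(vals, W).I,
                }
            )
            for j in sel:
                if j not in selected_union:
                    selected_union.append(j)
        selected_union.sort()
        return basis, pd.DataFrame(psr_rows), pd.DataFrame(sel_rows), selected_union

    def _ev_scores(self, basis: pe.EigenBasis, selected: list[int]) -> pd.DataFrame:
        cols = {}
        for j in selected:
            scores = dict(zip(basis.taxa, basis.vectors[:, j]))
            cols[f"EV{j + 1}"] = pe.assign_species_scores(
                self.specimens["species"], scores
            )
        return pd.DataFrame(cols, index=self.specimens.index)

    def _design(
        self, df: pd.DataFrame, ev_scores: pd.DataFrame | None
    ) -> pls.DesignMatrix:
        return pls.encode_design(
            df[["latitude", "longitude", "origin", "collection"]],
            df[[f"habitat_{t}" for t in TRAITS]].rename(
                columns=lambda c: c.removeprefix("habitat_")
            ),
            ev_scores,
        )

    def _responses(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for t in TRAITS:
            v = np.log10(df[f"fur_{t}"].to_numpy(float))
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero variance in fur_{t}")
            cols.append((v - v.mean()) / sd)
        return np.column_stack(cols)

    def _fit_plsr_model(
        self,
        df: pd.DataFrame,
        ev_scores: pd.DataFrame | None,
        responses: list[str],
        rng: np.random.Generator,
    ):
        design = self._design(df, ev_scores)
        Y = self._responses(df)
        idx = [TRAITS.index(t) for t in responses]
        model = pls.PLSRegression(
            Y[:, idx],
            design,
            y_names=[f"fur_{t}" for t in responses],
            standardize=False,
        )
        res = model.fit(
            select=True,
            folds=self.config.cv_folds,
            seed=rng,
            q2_threshold=self.config.q2_threshold,
            stratify=df["species"].to_numpy() if df["species"].nunique() > 1 else None,
        )
        if res.significant:
            res.bootstrap(self.config.bootstrap_B, rng)
        return res, design

    # ------------------------------------------------------------------ fit

    def fit(self) -> "AnalysisResults":
        """Run every stage and return the result bundle (deterministic in
        the config seed)."""
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        repeatability = self._repeatability()
        anova = self._anova()
        basis, psr, selection, selected = self._phylogenetics(self.tree)
        ev_scores = self._ev_scores(basis, selected) if selected else None

        global_models: dict[str, pls.PLSResults] = {}
        res, design = self._fit_plsr_model(
            self.specimens, ev_scores, list(TRAITS), rng
        )
        global_models["synthetic_colouration"] = res
        if cfg.single_response_models:
            for t in TRAITS:
                global_models[f"log10_{t}"], _ = self._fit_plsr_model(
                    self.specimens, ev_scores, [t], rng
                )

        per_species: dict[str, pls.PLSResults] = {}
        counts = self.specimens["species"].value_counts()
        for sp in [s for s in self.tree.taxa if counts.get(s, 0) >= cfg.per_species_min_n]:
            sub = self.specimens[self.specimens["species"] == sp].reset_index(drop=True)
            try:
                per_species[sp], _ = self._fit_plsr_model(sub, None, list(TRAITS), rng)
            except ValueError:
                continue  # degenerate subset (e.g. zero-variance column)

        correlations = self._correlations(ev_scores)
        partition = variance_partition(
            global_models["synthetic_colouration"], design.groups
        )
        return AnalysisResults(
            analysis=self,
            eigenbasis=basis,
            repeatability=repeatability,
            anova=anova,
            psr=psr,
            eigenvector_selection=selection,
            selected_eigenvectors=selected,
            global_models=global_models,
            per_species_models=per_species,
            correlations=correlations,
            partition=partition,
            design_groups=list(design.groups),
            config_hash=cfg.hash(),
            seed=cfg.seed,
        )

    def _correlations(self, ev_scores: pd.DataFrame | None) -> pd.DataFrame:
        """Fur-habitat correlations per trait: partial (controlling origin)
        and residual (controlling geography, origin and eigenvectors)."""
        df = self.specimens
        origin = pd.get_dummies(df["origin"], drop_first=True).to_numpy(float)
        # collection labels already nest the field/museum origin
        blocks = [
            df[["latitude", "longitude"]].to_numpy(float),
            pd.get_dummies(df["collection"], drop_first=True).to_numpy(float),
        ]
        if ev_scores is not None:
            blocks.append(ev_scores.to_numpy(float))
        Zfull = np.hstack(blocks)
        rows = []
        for t in TRAITS:
            fur = np.log10(df[f"fur_{t}"].to_numpy(float))
            hab = np.log10(df[f"habitat_{t}"].to_numpy(float))
            r_part, p_part = sc.partial_pearson(fur, hab, origin)
            r_res, p_res = sc.partial_pearson(fur, hab, Zfull)
            rows.append(
                {
                    "trait": t,
                    "partial_r": r_part,
                    "partial_p": p_part,
                    "residual_r": r_res,
                    "residual_p": p_res,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class AnalysisResults:
    """Full report bundle: one table per Results section, plus metadata."""

    analysis: CamouflageAnalysis
    eigenbasis: pe.EigenBasis
    repeatability: pd.DataFrame
    anova: pd.DataFrame
    psr: pd.DataFrame
    eigenvector_selection: pd.DataFrame
    selected_eigenvectors: list[int]
    global_models: dict[str, pls.PLSResults]
    per_species_models: dict[str, pls.PLSResults]
    correlations: pd.DataFrame
    partition: dict[str, float]
    design_groups: list[str]
    config_hash: str
    seed: int

    def block_recovery(self, block: str = "habitat") -> dict:
        """Block-level evidence from the global multi-response model.

        Returns the block's summed importance share, the block-total
        coefficient per response with bootstrap SE and p, and ``flagged``:
        True when the share exceeds 5% and the block total is positive and
        significant (p < 0.05) for every response.
        """
        g = self.global_models["synthetic_colouration"]
        if not g.significant:
            return {"share": 0.0, "flagged": False}
        names = g.model.x_names
        idx = [i for i, grp in enumerate(self.design_groups) if grp == block]
        if not idx:
            raise ValueError(f"no predictors in block {block!r}")
        shares, _ = g.importance()
        share = float(np.sum(shares[idx]))
        weights = np.zeros(len(names))
        weights[idx] = 1.0
        # one coefficient for the synthetic response: block total averaged
        # over the (standardized, strongly correlated) response traits
        est_q, _, _ = g._boot.linear_combination(g.fit_.beta, weights)
        est = float(np.mean(est_q))
        draws = g._boot.betas[:, idx, :].sum(axis=1).mean(axis=1)
        se = float(draws.std(ddof=1))
        if se > 0:
            from scipy import stats as _st

            p = float(2 * _st.norm.sf(abs(est / se)))
        else:
            p = 0.0 if est != 0 else 1.0
        flagged = share > 0.05 and est > 0 and p < 0.05
        return {
            "share": share,
            "estimate": est,
            "se": se,
            "p": p,
            "per_response_estimate": est_q,
            "flagged": flagged,
        }

    def global_summary(self) -> pd.DataFrame:
        tables = []
        for name, res in self.global_models.items():
            t = res.summary()
            t.insert(0, "model", name)
            t["explained_variance_pct"] = res.explained_variance
            t["n_components"] = res.n_components
            tables.append(t)
        return pd.concat(tables, ignore_index=True)

    def per_species_summary(self) -> pd.DataFrame:
        if not self.per_species_models:
            return pd.DataFrame()
        tables = []
        for sp, res in self.per_species_models.items():
            t = res.summary()
            t.insert(0, "species", sp)
            t["explained_variance_pct"] = res.explained_variance
            t["n_components"] = res.n_components
            tables.append(t)
        return pd.concat(tables, ignore_index=True)

    def summary(self) -> str:
        """Human-readable digest of the main findings."""
        lines = [
            f"Camouflage analysis (config {self.config_hash}, seed {self.seed})",
            f"  specimens: {len(self.analysis.specimens)}, "
            f"species: {self.analysis.specimens['species'].nunique()}",
        ]
        if not self.repeatability.empty:
            taus = self.repeatability.groupby("measure")["tau"].min()
            for measure, tau in taus.items():
                lines.append(f"  repeatability ({measure}): min tau = {tau:.3f}")
        lines.append(
            "  species ANOVA: min F = {:.2f} (fur), {:.2f} (habitat)".format(
                self.anova.query("measure=='fur'")["F"].min(),
                self.anova.query("measure=='habitat'")["F"].min(),
            )
        )
        lines.append(
            "  PSR mean deviation: "
            + ", ".join(
                f"{r.trait}={r.mean_deviation:+.3f}" for r in self.psr.itertuples()
            )
        )
        sel = ", ".join(f"EV{j + 1}" for j in self.selected_eigenvectors) or "none"
        lines.append(f"  selected eigenvectors: {sel}")
        g = self.global_models["synthetic_colouration"]
        lines.append(
            f"  global PLSR: {g.n_components} component(s), "
            f"{g.explained_variance:.1f}% variance explained"
        )
        lines.append(
            "  variance partition: "
            + ", ".join(f"{k}={v:.1f}%" for k, v in sorted(self.partition.items()))
        )
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        """Write all tables as CSV plus a metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tbl in (
            ("repeatability", self.repeatability),
            ("anova", self.anova),
            ("psr", self.psr),
            ("eigenvector_selection", self.eigenvector_selection),
            ("global_plsr", self.global_summary()),
            ("per_species_plsr", self.per_species_summary()),
            ("correlations", self.correlations),
        ):
            tbl = tbl.copy()
            tbl["config_hash"] = self.config_hash
            tbl["seed"] = self.seed
            tbl.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
        ev_tbl = pd.DataFrame(
            self.eigenbasis.vectors,
            index=pd.Index(self.eigenbasis.taxa, name="taxon"),
            columns=[f"EV{j + 1}" for j in range(self.eigenbasis.m)],
        )
        ev_tbl.loc["<eigenvalue>"] = self.eigenbasis.eigenvalues
        ev_tbl.to_csv(outdir / "eigenvectors.csv", float_format="%.10g")
        meta = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "algorithm": "PVR/PSR + NIPALS-PLS2",
            "selected_eigenvectors": [j + 1 for j in self.selected_eigenvectors],
            "variance_partition_pct": self.partition,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def run_full(config: RunConfig) -> AnalysisResults:
    """Load inputs per config, run the full analysis, optionally write it."""
    result = CamouflageAnalysis.from_config(config).fit()
    if config.output_dir:
        result.write(config.output_dir)
    return result


def sensitivity_rerun(
    analysis: CamouflageAnalysis, alternative_tree: pe.PhyloTree | str
) -> pd.DataFrame:
    """Re-run the phylogeny-dependent stages under an alternative topology.

    Returns a per-predictor delta table for the global multi-response model:
    weight, importance share and importance flag under each tree.
    """
    alt = (
        alternative_tree
        if isinstance(alternative_tree, pe.PhyloTree)
        else pe.parse_newick(alternative_tree)
    )
    if set(alt.taxa) != set(analysis.tree.taxa):
        raise ValueError("alternative tree must carry the same taxa")
    base = analysis.fit()
    alt_analysis = CamouflageAnalysis(analysis.specimens, alt, analysis.config)
    other = alt_analysis.fit()
    rows = []
    for res, tag in ((base, "base"), (other, "alternative")):
        m = res.global_models["synthetic_colouration"]
        shares, flags = m.importance()
        for name, w, s, f in zip(
            m.model.x_names, m.fit_.W[:, 0], shares, flags
        ):
            rows.append(
                {"tree": tag, "predictor": name, "W1": w, "share": s, "important": f}
            )
    wide = pd.DataFrame(rows).pivot(
        index="predictor", columns="tree", values=["W1", "share", "important"]
    )
    out = pd.DataFrame(
        {
            "predictor": wide.index,
            "W1_base": wide[("W1", "base")],
            "W1_alternative": wide[("W1", "alternative")],
            "delta_W1": wide[("W1", "alternative")] - wide[("W1", "base")],
            "share_base": wide[("share", "base")],
            "share_alternative": wide[("share", "alternative")],
            "flag_changed": wide[("important", "base")]
            != wide[("important", "alternative")],
        }
    ).reset_index(drop=True)
    return out
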