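"""Stage orchestration: simulate -> phenotypes -> GWAS -> selection -> prediction -> validation.

Each stage writes its artifacts under the output directory and is
idempotent: with unchanged inputs and seeds a rerun either skips (the
artifacts exist) or reproduces them byte for byte.  A ``manifest.json``
snapshotting the config, seeds and artifact checksums is maintained as
stages complete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from heatgp import __version__
from heatgp.config import RunConfig
from heatgp.errors import DataError
from heatgp.gwas import genomic_inflation, meta_multitrait, run_mlma
from heatgp.kinship import build_grm, estimate_greml
from heatgp.plinkio import read_plink, write_plink
from heatgp.predict import bull_weight, fit_bayesr, fit_bayesrc, fit_gblup, predict_gbv
from heatgp.prioritize import ld_prune, maf_filter, select_window_top_snps
from heatgp.reaction_norm import bull_dtd, fit_reaction_norm
from heatgp.simdata import StudyDesign, make_study_design, simulate_population
from heatgp.validate import lr_consistency, validation_report

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Runs the analysis stages against one output directory."""

    def __init__(self, config: RunConfig, out_dir: str | Path, force: bool = False):
        self.cfg = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.force = force
        self.traits = list(config["simulate"]["traits"])
        self._study = None
        self._design = None
        self._tds = {}
        self._dtds = {}
        self._varcomp = None
        self._gwas = {}
        self._meta = None
        self._topsnps = {}

    # -- manifest ----------------------------------------------------------

    def _update_manifest(self, stage: str, files: list[Path]) -> None:
        path = self.out / "manifest.json"
        manifest = json.loads(path.read_text()) if path.exists() else {
            "package_version": __version__,
            "config": self.cfg.raw,
            "seed": self.cfg.raw["seed"],
            "stages": {},
        }
        manifest["stages"][stage] = {
            str(f.relative_to(self.out)): _sha256(f) for f in files if f.exists()}
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def _done(self, *names: str) -> bool:
        return (not self.force) and all((self.out / n).exists() for n in names)

    def _require(self, name: str, stage: str) -> Path:
        p = self.out / name
        if not p.exists():
            raise DataError(f"missing artifact {p}: run the '{stage}' stage first")
        return p

    # -- stage 1: simulate -------------------------------------------------

    def simulate(self):
        files = ["genotypes.bed", "genotypes.bim", "genotypes.fam", "snp_map.tsv",
                 "individuals.tsv", "design.tsv"] + \
                [f"test_days_{t}.tsv" for t in self.traits] + \
                [f"truth_{t}.tsv" for t in self.traits]
        if self._study is not None:
            return self._study
        if self._done(*files):
            logger.info("simulate: artifacts present, skipping")
            return None
        sim = self.cfg["simulate"]
        study = simulate_population(
            n_discovery_cows=sim["n_discovery_cows"],
            n_reference_bulls=sim["n_reference_bulls"],
            daughters_per_bull=sim["daughters_per_bull"],
            n_validation_cows=sim["n_validation_cows"],
            map_config=sim["map_config"],
            fst=sim["fst"],
            mixture_proportions=sim["mixture_proportions"],
            h2_slope=sim["h2_slope"],
            h2_intercept=sim["h2_intercept"],
            genetic_variance_slope=sim["genetic_variance_slope"],
            genetic_variance_intercept=sim["genetic_variance_intercept"],
            traits=self.traits,
            climate=self.cfg["climate"],
            validation_breeds=sim.get("validation_breeds") or None,
            seed=self.cfg.raw["seed"],
        )
        n_cows = sim["n_discovery_cows"] + sim["n_validation_cows"]
        design = make_study_design(
            study.population, scenario=self.cfg.raw["scenario"],
            seed=self.cfg.raw["seed"] + 1,
            discovery_fraction=sim["n_discovery_cows"] / n_cows)

        geno = study.population.genotypes
        write_plink(geno, self.out / "genotypes")
        geno.snp_map.to_csv(self.out / "snp_map.tsv", sep="\t", index=False)
        study.population.individuals.to_csv(self.out / "individuals.tsv", sep="\t", index=False)
        design.to_frame().to_csv(self.out / "design.tsv", sep="\t", index=False)
        for t in self.traits:
            study.test_days[t].to_csv(self.out / f"test_days_{t}.tsv", sep="\t",
                                      index=False, float_format=FLOAT_FMT)
            model = study.models[t]
            truth = pd.DataFrame({
                "snp_id": geno.snp_ids[model.qtl_indices],
                "class": model.class_of_qtl,
                "effect_slope": model.effects_slope[model.qtl_indices],
                "effect_intercept": model.effects_intercept[model.qtl_indices],
            })
            truth.to_csv(self.out / f"truth_{t}.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
            tbv = pd.DataFrame({"individual_id": model.individual_ids,
                                "tbv_intercept": model.tbv_intercept,
                                "tbv_slope": model.tbv_slope})
            tbv.to_csv(self.out / f"tbv_{t}.tsv", sep="\t", index=False,
                       float_format=FLOAT_FMT)
        study.daughter_pedigree.to_csv(self.out / "daughter_pedigree.tsv",
                                       sep="\t", index=False)
        self._study, self._design = study, design
        self._update_manifest("simulate", [self.out / f for f in files])
        return study

    # -- loading helpers ---------------------------------------------------

    def genotypes(self):
        if self._study is not None:
            return self._study.population.genotypes
        self._require("genotypes.bed", "simulate")
        smap = pd.read_csv(self.out / "snp_map.tsv", sep="\t")
        tiers = dict(zip(smap["snp_id"], smap["tier"]))
        return read_plink(self.out / "genotypes", tier_map=tiers)

    def design(self) -> StudyDesign:
        if self._design is not None:
            return self._design
        df = pd.read_csv(self._require("design.tsv", "simulate"), sep="\t")
        disc = df.loc[df["role"] == "discovery", "individual_id"].to_numpy(dtype=object)
        ref = df.loc[df["role"] == "reference", "individual_id"].to_numpy(dtype=object)
        vsets = {}
        for role, grp in df[df["role"].str.startswith("validation:")].groupby("role"):
            name = role.split(":", 1)[1]
            a = grp.loc[grp["subset"] == "subset1", "individual_id"].to_numpy(dtype=object)
            b = grp.loc[grp["subset"] == "subset2", "individual_id"].to_numpy(dtype=object)
            vsets[name] = (a, b)
        self._design = StudyDesign(scenario=self.cfg.raw["scenario"],
                                   discovery_ids=disc, reference_ids=ref,
                                   validation_sets=vsets)
        return self._design

    # -- stage 2: reaction-norm trait deviations ---------------------------

    def derive_traits(self):
        files = [f"td_{t}.tsv" for t in self.traits] + [f"dtd_{t}.tsv" for t in self.traits]
        if self._done(*files) and not self._tds:
            for t in self.traits:
                self._tds[t] = pd.read_csv(self.out / f"td_{t}.tsv", sep="\t")
                self._dtds[t] = pd.read_csv(self.out / f"dtd_{t}.tsv", sep="\t")
            return self._tds, self._dtds
        if self._tds:
            return self._tds, self._dtds
        clim = self.cfg["climate"]
        ped_path = self._require("daughter_pedigree.tsv", "simulate")
        ped = pd.read_csv(ped_path, sep="\t")
        for t in self.traits:
            records = pd.read_csv(self._require(f"test_days_{t}.tsv", "simulate"), sep="\t") \
                if self._study is None else self._study.test_days[t]
            td = fit_reaction_norm(records, threshold=clim["threshold"],
                                   thi_max=clim["thi_max"],
                                   min_records=self.cfg["phenotypes"]["min_records"])
            td.to_csv(self.out / f"td_{t}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
            links = ped.loc[ped["trait"] == t, ["cow_id", "sire_id"]]
            dtd = bull_dtd(td, links)
            dtd.to_csv(self.out / f"dtd_{t}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
            self._tds[t], self._dtds[t] = td, dtd
        self._update_manifest("derive_traits", [self.out / f for f in files])
        return self._tds, self._dtds

    # -- stage 3: GRM + genomic heritability -------------------------------

    def grm_and_h2(self):
        if self._varcomp is not None:
            return self._varcomp
        path = self.out / "varcomp.tsv"
        if self._done("varcomp.tsv") and not self.force:
            self._varcomp = pd.read_csv(path, sep="\t").set_index("trait")
            return self._varcomp
        tds, _ = self.derive_traits()
        geno = self.genotypes()
        design = self.design()
        common = None
        for t in self.traits:
            ids = set(tds[t]["cow_id"])
            common = ids if common is None else (common & ids)
        disc = [i for i in design.discovery_ids if i in common]
        sub = maf_filter(geno.tier("array").subset_individuals(disc),
                         self.cfg["thresholds"]["maf"])
        grm = build_grm(sub)
        covar = self._breed_covariate(sub.breed)
        rows = []
        for t in self.traits:
            td = tds[t].set_index("cow_id").loc[disc]
            for trait_part in ("slope", "intercept"):
                vc = estimate_greml(td[f"{trait_part}_td"].to_numpy(), grm, covar)
                rows.append({"trait": t, "component": trait_part,
                             "sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2,
                             "h2": vc.h2, "se_h2": vc.se_h2, "n": len(disc)})
        vcdf = pd.DataFrame(rows)
        vcdf.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        self._varcomp = vcdf.set_index("trait")
        self._update_manifest("grm", [path])
        return self._varcomp

    @staticmethod
    def _breed_covariate(breeds) -> np.ndarray | None:
        labels = pd.unique(np.asarray(breeds))
        if len(labels) < 2:
            return None
        return (np.asarray(breeds) != labels[0]).astype(float)

    def h2_of(self, trait: str, component: str = "slope") -> float:
        vc = self.grm_and_h2()
        row = vc[(vc.index == trait) & (vc["component"] == component)]
        return float(row["h2"].iloc[0])

    # -- stage 4/5: GWAS + meta -------------------------------------------

    def gwas(self):
        files = [f"gwas_{t}.tsv" for t in self.traits]
        if self._gwas:
            return self._gwas
        if self._done(*files):
            for t in self.traits:
                self._gwas[t] = pd.read_csv(self.out / f"gwas_{t}.tsv", sep="\t")
            return self._gwas
        tds, _ = self.derive_traits()
        geno = self.genotypes()
        design = self.design()
        common = set.intersection(*[set(tds[t]["cow_id"]) for t in self.traits])
        disc = [i for i in design.discovery_ids if i in common]
        geno_disc = geno.subset_individuals(disc)
        seq = maf_filter(geno_disc, self.cfg["thresholds"]["maf"])
        grm = build_grm(seq.tier("array"))
        covar = self._breed_covariate(seq.breed)
        vcdf = self.grm_and_h2()
        for t in self.traits:
            y = tds[t].set_index("cow_id").loc[disc, "slope_td"].to_numpy()
            row = vcdf[(vcdf.index == t) & (vcdf["component"] == "slope")]
            vc = (float(row["sigma_g2"].iloc[0]), float(row["sigma_e2"].iloc[0]))
            res = run_mlma(y, seq, grm, covariates=covar, variance_components=vc)
            res.to_csv(self.out / f"gwas_{t}.tsv", sep="\t", index=False,
                       float_format=FLOAT_FMT)
            self._gwas[t] = res
            logger.info("GWAS %s: lambda = %.3f", t, genomic_inflation(res))
        self._update_manifest("gwas", [self.out / f for f in files])
        return self._gwas

    def meta(self):
        if self._meta is not None:
            return self._meta
        path = self.out / "gwas_meta.tsv"
        if self._done("gwas_meta.tsv"):
            self._meta = pd.read_csv(path, sep="\t")
            return self._meta
        gwas = self.gwas()
        self._meta = meta_multitrait([gwas[t] for t in self.traits])
        self._meta.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        self._update_manifest("meta", [path])
        return self._meta

    # -- stage 6: top-SNP selection ---------------------------------------

    def select(self):
        if self._topsnps:
            return self._topsnps
        thresholds = self.cfg["selection"]["neg_log10_thresholds"]
        names = [f"topsnps_{t}_thr{thr:g}.txt" for t in self.traits for thr in thresholds]
        names += [f"topsnps_meta_thr{thr:g}.txt" for thr in thresholds]
        if self._done(*names):
            for n in names:
                key = n[len("topsnps_"):-len(".txt")]
                self._topsnps[key] = [l.strip() for l in (self.out / n).read_text().splitlines() if l.strip()]
            return self._topsnps
        gwas = self.gwas()
        meta = self.meta()
        geno = self.genotypes()
        design = self.design()
        disc_geno = maf_filter(geno.subset_individuals(list(design.discovery_ids)),
                               self.cfg["thresholds"]["maf"])
        sources = {t: (gwas[t], "single_trait") for t in self.traits}
        sources["meta"] = (meta, "meta")
        written = []
        for name, (table, source) in sources.items():
            scores = dict(zip(table["snp_id"], table["neg_log10_p"]))
            for thr in thresholds:
                cfg = self.cfg.selection(threshold=thr)
                elected = select_window_top_snps(table, config=cfg, source=source)
                if len(elected):
                    pruned = ld_prune(disc_geno, elected.snp_ids, config=cfg,
                                      scores=scores, source=source)
                    pruned.n_before_prune = elected.n_before_prune
                else:
                    pruned = elected
                key = f"{name}_thr{thr:g}"
                out = self.out / f"topsnps_{key}.txt"
                pruned.write(out, provenance_path=self.out / f"topsnps_{key}.provenance.tsv")
                self._topsnps[key] = list(pruned.snp_ids)
                written.append(out)
        self._update_manifest("select", written)
        return self._topsnps

    # -- stage 7: genomic prediction --------------------------------------

    def predict(self):
        gbv_files = [f"gbv_{t}_{m}.tsv" for t in self.traits
                     for m in ("bayesr", "bayesrc", "gblup1", "gblup2")]
        if self._done(*gbv_files):
            return {f: pd.read_csv(self.out / f, sep="\t", index_col=0)["gbv"]
                    for f in gbv_files}
        _, dtds = self.derive_traits()
        geno = self.genotypes()
        design = self.design()
        topsnps = self.select()
        pcfg = self.cfg["prediction"]
        thr, source = pcfg["topsnp_threshold"], pcfg["topsnp_source"]
        mcmc = self.cfg.mcmc()

        val_ids = np.concatenate([design.validation_ids(n)
                                  for n in sorted(design.validation_sets)])
        results = {}
        written = []
        lr_rows = []
        for t in self.traits:
            dtd = dtds[t].set_index("bull_id")
            ref_ids = [b for b in design.reference_ids if b in dtd.index]
            y = dtd.loc[ref_ids, "dtd_slope"]
            h2 = self.h2_of(t, "slope")
            weights = np.array([bull_weight(h2, pcfg["c"], int(p))
                                for p in dtd.loc[ref_ids, "p"]]) \
                if pcfg["weight_records"] else None

            array_geno = maf_filter(geno.tier("array"), self.cfg["thresholds"]["maf"])
            key = (f"{t}_thr{thr:g}" if source == "single_trait" else f"meta_thr{thr:g}")
            extra = [s for s in topsnps.get(key, []) if s not in set(array_geno.snp_ids)]
            combined = geno.subset_snps(snp_ids=list(array_geno.snp_ids) + extra)
            order = np.lexsort((combined.snp_map["position_bp"].to_numpy(),
                                combined.snp_map["chromosome"].to_numpy()))
            combined = combined.subset_snps(mask=order)
            annot = (~np.isin(combined.snp_ids, array_geno.snp_ids)).astype(np.int64)

            ref_rows_a = array_geno.subset_individuals(ref_ids)
            val_rows_a = array_geno.subset_individuals(list(val_ids))
            ref_rows_c = combined.subset_individuals(ref_ids)
            val_rows_c = combined.subset_individuals(list(val_ids))
            covar = self._breed_covariate(ref_rows_a.breed)

            post_r = fit_bayesr(y.to_numpy(), ref_rows_a, weights=weights,
                                covariates=covar, mcmc=mcmc)
            results[f"gbv_{t}_bayesr.tsv"] = predict_gbv(post_r, val_rows_a)
            post_c = fit_bayesrc(y.to_numpy(), ref_rows_c, weights=weights,
                                 covariates=covar, classes=annot, mcmc=mcmc)
            results[f"gbv_{t}_bayesrc.tsv"] = predict_gbv(post_c, val_rows_c)
            self._write_posterior(post_r, self.out / f"posterior_{t}_bayesr.tsv")
            self._write_posterior(post_c, self.out / f"posterior_{t}_bayesrc.tsv")

            if pcfg.get("gblup", True):
                both = array_geno.subset_individuals(list(ref_ids) + list(val_ids))
                both_c = combined.subset_individuals(list(ref_ids) + list(val_ids))
                # SNPs can lose polymorphism within the ref+val subset
                both = both.subset_snps(mask=np.flatnonzero(both.maf() > 0))
                grm1 = build_grm(both)
                gbv1, _ = fit_gblup(y, weights=weights, grms=grm1, covariates=covar)
                results[f"gbv_{t}_gblup1.tsv"] = gbv1.loc[val_ids]
                if annot.any():
                    top_sub = both_c.subset_snps(mask=np.flatnonzero(annot))
                    top_sub = top_sub.subset_snps(mask=np.flatnonzero(top_sub.maf() > 0))
                    grm_top = build_grm(top_sub)
                    gbv2, _ = fit_gblup(y, weights=weights, grms=[grm1, grm_top],
                                        covariates=covar)
                else:
                    gbv2 = gbv1
                results[f"gbv_{t}_gblup2.tsv"] = gbv2.loc[val_ids]

                # LR-method: GBLUP from a reduced reference set
                rng = np.random.default_rng(self.cfg.raw["seed"] + 7)
                n_part = int(len(ref_ids) * self.cfg["validation"]["lr_partial_fraction"])
                part = list(rng.permutation(np.asarray(ref_ids, dtype=object))[:n_part])
                w_part = None if weights is None else \
                    weights[[ref_ids.index(b) for b in part]]
                cv_part = None if covar is None else covar[[ref_ids.index(b) for b in part]]
                gbv_p, _ = fit_gblup(y.loc[part], weights=w_part, grms=grm1,
                                     covariates=cv_part)
                lr = lr_consistency(gbv1.loc[val_ids], gbv_p.loc[val_ids])
                lr_rows.append({"trait": t, "method": "gblup1",
                                "corr_whole_partial": lr.corr_whole_partial,
                                "b_w_p": lr.b_w_p})

        for fname, series in results.items():
            series.rename_axis("individual_id").to_frame().to_csv(
                self.out / fname, sep="\t", float_format=FLOAT_FMT)
            written.append(self.out / fname)
        if lr_rows:
            pd.DataFrame(lr_rows).to_csv(self.out / "lr_report.tsv", sep="\t",
                                         index=False, float_format=FLOAT_FMT)
        self._update_manifest("predict", written)
        return results

    @staticmethod
    def _write_posterior(post, path: Path) -> None:
        df = pd.DataFrame({"snp_id": post.snp_ids,
                           "effect_mean": post.snp_effect_mean,
                           "annotation": post.annotation})
        for k in range(4):
            df[f"p_class{k}"] = post.class_prob[:, k]
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)

    # -- stage 8: validation ----------------------------------------------

    def validate(self) -> pd.DataFrame:
        path = self.out / "validation_report.tsv"
        if self._done("validation_report.tsv"):
            return pd.read_csv(path, sep="\t")
        tds, _ = self.derive_traits()
        design = self.design()
        gbvs = self.predict()
        rows = []
        for t in self.traits:
            phen = tds[t].set_index("cow_id")["slope_td"]
            h2 = self.h2_of(t, "slope")
            for method in ("bayesr", "bayesrc", "gblup1", "gblup2"):
                fname = f"gbv_{t}_{method}.tsv"
                if fname not in gbvs:
                    continue
                gbv = gbvs[fname]
                for name, (a, b) in design.validation_sets.items():
                    # cows dropped by the phenotype identifiability screen
                    # cannot enter the accuracy computation
                    avail = set(phen.index) & set(gbv.index)
                    a = np.asarray([i for i in a if i in avail], dtype=object)
                    b = np.asarray([i for i in b if i in avail], dtype=object)
                    rep = validation_report(t, method, gbv, phen, (a, b), h2)
                    rows.append({
                        "trait": t, "validation_set": name, "method": method,
                        "accuracy": rep.accuracy, "accuracy_se": rep.accuracy_se,
                        "bias_b": rep.bias_b,
                        "accuracy_subset1": rep.subset_accuracies[0],
                        "accuracy_subset2": rep.subset_accuracies[1],
                        "h2_used": h2,
                    })
        report = pd.DataFrame(rows)
        report.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        self._update_manifest("validate", [path])
        return report

    # -- everything --------------------------------------------------------

    def run_all(self) -> pd.DataFrame:
        self.simulate()
        self.derive_traits()
        self.grm_and_h2()
        self.gwas()
        self.meta()
        self.select()
        self.predict()
        return self.validate()


def run_pipeline(config: RunConfig, out_dir, stage: str = "all",
                 force: bool = False):
    """Entry point used by the CLI: run one stage (or ``all``)."""
    config.validate()
    pipe = Pipeline(config, out_dir, force=force)
    stages = {
        "simulate": pipe.simulate,
        "derive-traits": pipe.derive_traits,
        "grm": pipe.grm_and_h2,
        "gwas": pipe.gwas,
        "meta": pipe.meta,
        "select": pipe.select,
        "predict": pipe.predict,
        "validate": pipe.validate,
        "all": pipe.run_all,
    }
    if stage not in stages:
        raise DataError(f"unknown stage {stage!r}; choose from {sorted(stages)}")
    return stages[stage]()
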