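"""Read/write a simulated study as a directory of plain-text tables.

Layout (all tab-separated, one ``meta.yaml`` describing every table and a
``truth.yaml`` with the planted ground truth, consumed only by tests):

    meta.yaml                 mode, trait metadata, outcome families
    truth.yaml                planted effects / expected survivors
    eqtl_<gene>_<tissue>.tsv  cis-eQTL summary statistics (drug-target mode)
    hba1c_<stratum>.tsv       exposure GWAS per stratum
    t2d.tsv                   positive-control GWAS (drug-target mode)
    outcome_<name>.tsv        outcome GWAS
    ld_matrix.tsv             square r² matrix, ld_variants.tsv sidecar
    genes.tsv                 gene annotations (drug-target mode)
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .ld_clump import read_ld_matrix, write_ld_matrix
from .sumstats import (
    SummaryStatTable,
    TraitMeta,
    read_gene_annotations,
    read_sumstats,
    write_gene_annotations,
    write_sumstats,
)
from .synthetic import GwsStudy, SyntheticStudy


def _meta_dict(meta: TraitMeta) -> dict:
    return {
        "trait_id": meta.trait_id,
        "trait_name": meta.trait_name,
        "scale": meta.scale,
        "units": meta.units,
        "stratum": meta.stratum,
        "sample_size": int(meta.sample_size),
        "n_cases": None if meta.n_cases is None else int(meta.n_cases),
    }


def _meta_from_dict(d: dict) -> TraitMeta:
    return TraitMeta(**d)


def write_drug_target_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"mode": "drug_target", "eqtls": [], "hba1c": {}, "outcomes": []}
    for (gene_id, tissue), table in study.eqtls.items():
        fname = f"eqtl_{gene_id}_{tissue}.tsv"
        write_sumstats(table, out / fname)
        meta["eqtls"].append(
            {"gene_id": gene_id, "tissue": tissue, "file": fname,
             "meta": _meta_dict(table.meta)}
        )
    for stratum, table in study.hba1c.items():
        fname = f"hba1c_{stratum}.tsv"
        write_sumstats(table, out / fname)
        meta["hba1c"][stratum] = {"file": fname, "meta": _meta_dict(table.meta)}
    write_sumstats(study.t2d, out / "t2d.tsv")
    meta["t2d"] = {"file": "t2d.tsv", "meta": _meta_dict(study.t2d.meta)}
    for name, table, family in study.outcomes:
        fname = f"outcome_{name}.tsv"
        write_sumstats(table, out / fname)
        meta["outcomes"].append(
            {"name": name, "family": family, "file": fname,
             "meta": _meta_dict(table.meta)}
        )
    write_ld_matrix(study.ld, out / "ld_matrix.tsv", out / "ld_variants.tsv")
    write_gene_annotations(study.genes, out / "genes.tsv")

    truth = study.truth
    truth_doc = {
        "survivors": dict(truth.survivors),
        "instrumentable": list(truth.instrumentable),
        "uninstrumentable": list(truth.uninstrumentable),
        "gamma": {k: float(v) for k, v in truth.gamma.items()},
        "alpha_t2d": {k: float(v) for k, v in truth.alpha_t2d.items()},
        "theta_cancer": {
            f"{gene}|{outcome}": float(v)
            for (gene, outcome), v in truth.theta_cancer.items()
        },
        "variant_gene": dict(truth.variant_gene),
        "variant_class": dict(truth.variant_class),
        "seed": int(truth.config.seed),
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(truth_doc, sort_keys=True))
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def write_gws_study(study: GwsStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"mode": "conventional", "hba1c": {}, "outcomes": []}
    for stratum, table in study.hba1c.items():
        fname = f"hba1c_{stratum}.tsv"
        write_sumstats(table, out / fname)
        meta["hba1c"][stratum] = {"file": fname, "meta": _meta_dict(table.meta)}
    for name, table, family in study.outcomes:
        fname = f"outcome_{name}.tsv"
        write_sumstats(table, out / fname)
        meta["outcomes"].append(
            {"name": name, "family": family, "file": fname,
             "meta": _meta_dict(table.meta)}
        )
    write_ld_matrix(study.ld, out / "ld_matrix.tsv", out / "ld_variants.tsv")
    (out / "truth.yaml").write_text(yaml.safe_dump(study.truth, sort_keys=True))
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


class StudyDir:
    """Lazy accessor over a study directory written by the functions above."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.meta = yaml.safe_load((self.path / "meta.yaml").read_text())

    @property
    def mode(self) -> str:
        return self.meta["mode"]

    def _read(self, entry: dict) -> SummaryStatTable:
        return read_sumstats(self.path / entry["file"], _meta_from_dict(entry["meta"]))

    def eqtls(self) -> dict:
        return {
            (e["gene_id"], e["tissue"]): self._read(e)
            for e in self.meta.get("eqtls", [])
        }

    def hba1c(self) -> dict:
        return {s: self._read(e) for s, e in self.meta["hba1c"].items()}

    def t2d(self) -> SummaryStatTable:
        return self._read(self.meta["t2d"])

    def outcomes(self) -> list:
        return [
            (e["name"], self._read(e), e["family"]) for e in self.meta["outcomes"]
        ]

    def ld(self):
        return read_ld_matrix(
            self.path / "ld_matrix.tsv", self.path / "ld_variants.tsv"
        )

    def genes(self):
        return read_gene_annotations(self.path / "genes.tsv")

    def truth(self) -> dict:
        return yaml.safe_load((self.path / "truth.yaml").read_text())
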