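"""Shared fixtures: a small synthetic dataset and a runnable pipeline config."""

from __future__ import annotations

import shutil
from pathlib import Path

import pytest
import yaml

from tadlink.motif import load_builtin_pwm
from tadlink.synthetic_data import SimConfig, generate_dataset, write_dataset

TEST_SEED = 1


@pytest.fixture(scope="session")
def builtin_pwm():
    return load_builtin_pwm()


@pytest.fixture(scope="session")
def small_sim_config():
    # compact genome so dataset generation stays fast in every test run
    return SimConfig(
        n_chromosomes=2,
        chrom_length=500_000,
        n_tads=10,
        n_genes=120,
        n_peaks=400,
        seed=TEST_SEED,
    )


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_sim_config, builtin_pwm):
    out = tmp_path_factory.mktemp("dataset")
    bundle = generate_dataset(small_sim_config, motif_consensus=builtin_pwm.consensus)
    manifest = write_dataset(bundle, out)
    return out, bundle, manifest


@pytest.fixture(scope="session")
def pipeline_config(dataset_dir, tmp_path_factory):
    out_dir, bundle, manifest = dataset_dir
    workdir = tmp_path_factory.mktemp("run")
    pwm_src = Path(__file__).parent.parent / "src" / "tadlink" / "data" / "nfat_ap1_synthetic.jaspar"
    shutil.copy(pwm_src, workdir / "pwm.jaspar")
    cfg = {
        "inputs": {
            "genome_fasta": str(out_dir / "genome.fa"),
            "genes_gtf": str(out_dir / "genes.gtf"),
            "tads_bed": str(out_dir / "tads.bed"),
            "master_peaks": str(out_dir / "peaks/master.narrowPeak"),
            "sample_peaks": {
                sid: str(out_dir / rel)
                for sid, rel in manifest["paths"]["sample_peaks"].items()
            },
            "atac_counts": str(out_dir / "atac_counts.tsv"),
            "rna_counts": str(out_dir / "rna_counts.tsv"),
            "groups": str(out_dir / "groups.tsv"),
            "motif_pwm": str(workdir / "pwm.jaspar"),
        },
        "analysis": {"seed": TEST_SEED},
        "motif": {"enabled": True, "scan_p": 1.0e-4},
        "output_dir": str(workdir / "out"),
    }
    cfg_path = workdir / "run.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return cfg_path
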