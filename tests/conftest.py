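import numpy as np
import pytest

from beadcast.fixtures import (
    gen_bilayer,
    toy_amphiphile_template,
    toy_residue_map,
    write_template_files,
)
from beadcast.io_formats import write_residue_map, write_structure
from beadcast.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def toy_template():
    return toy_amphiphile_template()


@pytest.fixture(scope="session")
def toy_map(toy_template):
    return toy_residue_map(toy_template)


def write_top(path, entries):
    with open(path, "w") as fh:
        fh.write("; CG system topology\n[ molecules ]\n")
        for name, count in entries:
            fh.write(f"{name} {count}\n")


def make_pipeline_inputs(workdir, cg, top, template, **config_kwargs):
    """Write a full input tree (structure, top, map, templates) and return a config."""
    workdir.mkdir(parents=True, exist_ok=True)
    write_template_files(template, workdir / "templates")
    write_residue_map(toy_residue_map(template), workdir / "residues.map")
    write_structure(cg, workdir / "cg.pdb", "pdb")
    write_top(workdir / "cg.top", top.entries)
    return PipelineConfig(
        cg_structure=str(workdir / "cg.pdb"),
        cg_topology=str(workdir / "cg.top"),
        residue_map=str(workdir / "residues.map"),
        template_dir=str(workdir / "templates"),
        output_dir=str(workdir / "out"),
        **config_kwargs,
    )


@pytest.fixture()
def small_bilayer(toy_template):
    return gen_bilayer(2, 2, seed=11, template=toy_template)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
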