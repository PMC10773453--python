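"""Shared fixtures: benchmark datasets exported from the installed R
phytools library (no network), and small synthetic trees."""

import subprocess
from pathlib import Path

import pytest

import pcmkit

_EXPORT_R = r"""
suppressPackageStartupMessages(library(phytools))
args <- commandArgs(trailingOnly=TRUE)
out <- args[1]
data(sunfish.tree); data(sunfish.data)
write.tree(as.phylo(sunfish.tree), file.path(out,"sunfish.nwk"))
write.csv(data.frame(tip=rownames(sunfish.data),
                     feeding_mode=sunfish.data$feeding.mode),
          file.path(out,"sunfish.csv"), row.names=FALSE)
data(eel.tree); data(eel.data)
write.tree(eel.tree, file.path(out,"eel.nwk"))
write.csv(data.frame(tip=rownames(eel.data), max_tl_cm=eel.data$Max_TL_cm),
          file.path(out,"eel.csv"), row.names=FALSE)
data(liolaemid.tree); data(liolaemid.data)
write.tree(liolaemid.tree, file.path(out,"liolaemid.nwk"))
write.csv(data.frame(tip=rownames(liolaemid.data),
                     parity_mode=liolaemid.data$parity_mode),
          file.path(out,"liolaemid.csv"), row.names=FALSE)
data(tropidurid.tree); data(tropidurid.data)
write.simmap(tropidurid.tree, file.path(out,"tropidurid.simmap"))
write.csv(data.frame(tip=rownames(tropidurid.data), tropidurid.data),
          file.path(out,"tropidurid.csv"), row.names=FALSE)
data(elapidae.tree)
write.tree(elapidae.tree, file.path(out,"elapidae.nwk"))
data(cordylid.tree); data(cordylid.data)
write.tree(cordylid.tree, file.path(out,"cordylid.nwk"))
write.csv(data.frame(tip=rownames(cordylid.data), cordylid.data),
          file.path(out,"cordylid.csv"), row.names=FALSE)
data(anoletree); data(anole.data)
write.tree(as.phylo(anoletree), file.path(out,"anole.nwk"))
write.csv(data.frame(tip=rownames(anole.data), anole.data),
          file.path(out,"anole.csv"), row.names=FALSE)
data(vertebrate.tree); data(vertebrate.data)
write.tree(vertebrate.tree, file.path(out,"vertebrate.nwk"))
write.csv(data.frame(tip=rownames(vertebrate.data), vertebrate.data),
          file.path(out,"vertebrate.csv"), row.names=FALSE)
"""


@pytest.fixture(scope="session")
def refdata(tmp_path_factory) -> Path:
    """Benchmark trees/datasets exported from the local R phytools library."""
    out = tmp_path_factory.mktemp("refdata")
    script = out / "export.R"
    script.write_text(_EXPORT_R)
    res = subprocess.run(["Rscript", str(script), str(out)],
                         capture_output=True, text=True, timeout=300)
    if res.returncode != 0:
        raise RuntimeError(f"reference-data export failed:\n{res.stderr}")
    return out


@pytest.fixture()
def three_tip():
    return pcmkit.parse_tree("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture(scope="session")
def fixture20():
    """A 20-tip pure-birth fixture with a binary ER character."""
    return pcmkit.make_fixture(pcmkit.FixtureSpec(n_tips=20, seed=11))
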