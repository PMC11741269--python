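import json

import pytest

from crmkit.pipeline import demo_config, run_pipeline


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the bundled zero-noise demo config.

    Returns (config, report dict, output dir Path, truth dict).
    """
    outdir = tmp_path_factory.mktemp("demo_out")
    cfg = demo_config()
    cfg.outdir = str(outdir)
    report = run_pipeline(cfg)
    truth = json.loads((outdir / "truth.json").read_text())
    return cfg, report, outdir, truth
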