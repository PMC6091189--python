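import zipfile

import numpy as np
import pandas as pd
import pytest

from musclehca.batch import FOLDERS, RunConfig, run_batch
from musclehca.image_io import write_section
from musclehca.roi_export import decode_imagej_roi, encode_imagej_roi
from musclehca.synthetic import SynthParams, degrade, generate_section

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

PARAMS = SynthParams(
    n_fibers=90,
    cnf_fraction=0.3,
    satellites_per_fiber_dist={0: 0.6, 1: 0.4},
    vessels_per_fiber_dist={3: 0.5, 4: 0.5},
    channels=("laminin", "dapi", "pax7", "cd31"),
)
CHANNEL_MAP = {"laminin": 0, "dapi": 1, "pax7": 2, "cd31": 3}


@pytest.fixture(scope="module")
def image_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("images")
    for i in range(3):
        section, _ = generate_section(PARAMS, seed=30 + i)
        write_section(d / f"img{i}.tif", section,
                      channel_order=list(PARAMS.channels))
    return d


def base_config(image_dir, out_dir, **kw):
    defaults = dict(
        input_dir=str(image_dir),
        output_dir=str(out_dir),
        channel_map=dict(CHANNEL_MAP),
        scale_um_per_px=1.0,
        features=("morphometry", "cnf", "satellites", "vessels"),
        cartographies=("csa", "centronuclei"),
        run_id="t",
        seed=0,
    )
    defaults.update(kw)
    return RunConfig(**defaults)


@pytest.fixture(scope="module")
def batch_run(image_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("out")
    table = run_batch(base_config(image_dir, out))
    return out, table


class TestRunBatch:
    def test_folder_layout(self, batch_run):
        out, _ = batch_run
        folders = sorted(p.name for p in out.iterdir() if p.is_dir())
        assert folders == sorted(FOLDERS)
        assert (out / "RunGlobalResult_t.txt").exists()

    def test_one_global_row_per_image(self, batch_run):
        out, table = batch_run
        assert len(table) == 3
        assert table["Accepted"].sum() == 3
        per_fiber = sorted((out / "Results by file").glob("*_fibers.txt"))
        assert len(per_fiber) == 3

    def test_global_aggregates_match_per_fiber_tables(self, batch_run):
        out, table = batch_run
        for _, row in table.iterrows():
            per_fiber = pd.read_csv(
                out / "Results by file" / f"{row.Image}_fibers.txt", sep="\t")
            assert len(per_fiber) == row.NbFibers
            assert per_fiber["CSA"].mean() == pytest.approx(row.MeanCSA)
            assert 100 * per_fiber["IsCNF"].mean() == pytest.approx(row.PctCNF)

    def test_cartography_files_written(self, batch_run):
        out, table = batch_run
        for _, row in table.iterrows():
            for kind in ("csa", "centronuclei"):
                assert (out / "Cartography" / f"{row.Image}_{kind}.jpg").exists()
                assert (out / "Cartography" / f"{row.Image}_{kind}.png").exists()

    def test_roi_archives(self, batch_run):
        out, table = batch_run
        archives = sorted((out / "ROI").glob("*.zip"))
        assert len(archives) == 3
        with zipfile.ZipFile(archives[0]) as zf:
            names = zf.namelist()
            assert "index.csv" in names
            index = pd.read_csv(zf.open("index.csv"))
            assert set(index.roi_kind) == {"F", "CNF", "SC", "V"}
            # round-trip one polygon record
            entry = index.iloc[0].entry
            pts = decode_imagej_roi(zf.read(entry))
            assert pts.ndim == 2 and pts.shape[1] == 2

    def test_rerun_byte_identical(self, image_dir, tmp_path_factory, batch_run):
        out1, _ = batch_run
        out2 = tmp_path_factory.mktemp("out2")
        run_batch(base_config(image_dir, out2))
        for rel in ["RunGlobalResult_t.txt"] + [
            f"Results by file/img{i}_fibers.txt" for i in range(3)
        ]:
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes()
        for png in sorted((out1 / "Cartography").glob("*.png")):
            assert png.read_bytes() == (out2 / "Cartography" / png.name).read_bytes()

    def test_feature_subset_drops_columns(self, image_dir, tmp_path):
        table = run_batch(base_config(
            image_dir, tmp_path / "o", features=("morphometry",),
            cartographies=()))
        assert "PctCNF" not in table.columns
        assert "VesselsPerMm2" not in table.columns
        per_fiber = pd.read_csv(
            tmp_path / "o" / "Results by file" / "img0_fibers.txt", sep="\t")
        assert "NbCentroNuclei" not in per_fiber.columns

    def test_qc_failure_routed_to_artefacts(self, tmp_path):
        d = tmp_path / "in"
        d.mkdir()
        section, truth = generate_section(PARAMS, seed=50)
        bad, _ = degrade(section, truth, "broken_walls", 0.25, seed=1)
        write_section(d / "good.tif", section, channel_order=list(PARAMS.channels))
        write_section(d / "bad.tif", bad, channel_order=list(PARAMS.channels))
        out = tmp_path / "out"
        table = run_batch(base_config(d, out, artifact_tolerance=0.05))
        by_image = table.set_index("Image")
        assert by_image.loc["good", "Accepted"] == 1
        assert by_image.loc["bad", "Accepted"] == 0
        assert (out / "Artefacts" / "bad.tif").exists()
        assert not (out / "Results by file" / "bad_fibers.txt").exists()

    def test_empty_input_dir(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError):
            run_batch(base_config(tmp_path / "empty", tmp_path / "o"))


class TestRunConfigValidation:
    def test_laminin_always_required(self, tmp_path):
        with pytest.raises(ValueError, match="laminin"):
            RunConfig(input_dir=".", output_dir=".", channel_map={"dapi": 0})

    def test_feature_channel_dependencies(self):
        with pytest.raises(ValueError, match="dapi"):
            RunConfig(input_dir=".", output_dir=".",
                      channel_map={"laminin": 0}, features=("cnf",))
        with pytest.raises(ValueError, match="cd31"):
            RunConfig(input_dir=".", output_dir=".",
                      channel_map={"laminin": 0}, features=("vessels",))
        with pytest.raises(ValueError, match="typing"):
            RunConfig(input_dir=".", output_dir=".",
                      channel_map={"laminin": 0}, features=("typing",))

    def test_unknown_feature(self):
        with pytest.raises(ValueError, match="unknown features"):
            RunConfig(input_dir=".", output_dir=".",
                      channel_map={"laminin": 0}, features=("teleportation",))


class TestRoiCodec:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 500, (17, 2)).astype(np.int32)
        decoded = decode_imagej_roi(encode_imagej_roi(pts))
        np.testing.assert_array_equal(decoded, pts)


class TestCli:
    def test_cli_run_with_config(self, image_dir, tmp_path):
        from click.testing import CliRunner

        from musclehca.cli import main

        cfg = tmp_path / "cfg.toml"
        out = tmp_path / "cli_out"
        cfg.write_text(
            f'input_dir = "{image_dir}"\n'
            f'output_dir = "{out}"\n'
            'scale_um_per_px = 1.0\n'
            'features = ["morphometry", "cnf"]\n'
            'run_id = "cli"\n'
            "[channels]\nlaminin = 0\ndapi = 1\n"
        )
        result = CliRunner().invoke(main, ["run", "--config", str(cfg)])
        assert result.exit_code == 0, result.output
        assert (out / "RunGlobalResult_cli.txt").exists()

    def test_cli_typing_run(self, tmp_path):
        from click.testing import CliRunner

        from musclehca.cli import main

        d = tmp_path / "in"
        d.mkdir()
        params = SynthParams(n_fibers=60, type_mix={"IIA": 0.5, "IIX": 0.5},
                             channels=("laminin", "stain1", "stain2", "stain3"))
        section, _ = generate_section(params, seed=9)
        write_section(d / "ty.tif", section, channel_order=list(params.channels))
        cfg = tmp_path / "cfg.toml"
        out = tmp_path / "out"
        cfg.write_text(
            f'input_dir = "{d}"\noutput_dir = "{out}"\n'
            'scale_um_per_px = 1.0\nrun_id = "ty"\n'
            'features = ["morphometry", "typing"]\n'
            'cartographies = ["fibertype"]\n'
            "[channels]\nlaminin = 0\nstain1 = 1\nstain2 = 2\nstain3 = 3\n"
        )
        result = CliRunner().invoke(main, ["run", "--config", str(cfg)])
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out / "RunGlobalResult_ty.txt", sep="\t")
        assert "Threshold_stain1" in table.columns
        assert table.loc[0, "PctType_IIA"] == pytest.approx(50.0, abs=5.0)
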