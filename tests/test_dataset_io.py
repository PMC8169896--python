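"""TPS/CSV ingest, export and dataset assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphosus.dataset_io import (
    DatasetError,
    LandmarkConfiguration,
    TpsParseError,
    assemble_dataset,
    read_metadata,
    read_tps,
    read_xyz_table,
    write_tps,
)


def test_minimal_tps_record(tmp_path):
    f = tmp_path / "a.tps"
    f.write_text("LM=4\n0 0\n1 0\n1 1\n0 1\nID=s1\n")
    entries = read_tps(f)
    assert len(entries) == 1
    sid, config, curves = entries[0]
    assert sid == "s1"
    assert config.p == 4 and config.dimension == 2
    assert curves == []


def test_tps_curves_kept_separate_and_scale_applied(tmp_path):
    lines = ["LM=3", "0 0", "2 0", "1 1", "CURVES=1", "POINTS=4"]
    lines += [f"{i} {i+1}" for i in range(4)]
    lines += ["IMAGE=whatever.jpg", "SCALE=0.5", "ID=t7"]
    f = tmp_path / "c.tps"
    f.write_text("\n".join(lines) + "\n")
    (sid, config, curves), = read_tps(f)
    assert sid == "t7"
    assert config.p == 3
    assert len(curves) == 1 and curves[0].shape == (4, 2)
    # SCALE multiplies both landmarks and curve points
    assert np.allclose(config.points[1], [1.0, 0.0])
    assert np.allclose(curves[0][1], [0.5, 1.0])


def test_tps_3d_header_and_flip_y(tmp_path):
    f = tmp_path / "d.tps"
    f.write_text("LM3=3\n0 0 0\n1 2 3\n4 5 6\nID=x\n")
    (_, config, _), = read_tps(f)
    assert config.dimension == 3
    f2 = tmp_path / "e.tps"
    f2.write_text("LM=3\n0 1\n1 2\n2 0\nID=y\n")
    (_, flipped, _), = read_tps(f2, flip_y=True)
    assert np.allclose(flipped.points[:, 1], [-1, -2, 0])


@pytest.mark.parametrize(
    "content, match",
    [
        ("LM=3\n0 0\n1 1\nID=s2\n", "truncated"),
        ("LM=0\nID=z\n", "LM=0"),
        ("LM=2\n0 0\nfoo bar\nID=q\n", "non-numeric"),
    ],
)
def test_tps_malformed_inputs(tmp_path, content, match):
    f = tmp_path / "bad.tps"
    f.write_text(content)
    with pytest.raises(TpsParseError, match=match):
        read_tps(f)


def test_tps_round_trip_square(tmp_path, unit_square):
    f = tmp_path / "rt.tps"
    write_tps([("sq", unit_square, [])], f)
    (sid, config, _), = read_tps(f)
    assert sid == "sq"
    assert np.allclose(config.points, unit_square.points, atol=1e-6)


def test_write_tps_empty_and_nan(tmp_path):
    f = tmp_path / "empty.tps"
    write_tps([], f)
    assert read_tps(f) == []
    bad = LandmarkConfiguration(np.array([[0.0, 0], [1, 0], [0, 1]]))
    object.__setattr__(bad, "points", np.array([[np.nan, 0], [1, 0], [0, 1]]))
    with pytest.raises(DatasetError, match="non-finite"):
        write_tps([("b", bad, [])], tmp_path / "nan.tps")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    coords=st.lists(
        st.tuples(
            st.floats(-1e4, 1e4, allow_nan=False, width=32),
            st.floats(-1e4, 1e4, allow_nan=False, width=32),
        ),
        min_size=3,
        max_size=12,
    )
)
def test_tps_round_trip_property(tmp_path_factory, coords):
    """Round-tripping preserves ids, counts and coordinates to 1e-6."""
    pts = np.array(coords, dtype=float)
    config = LandmarkConfiguration(pts)
    f = tmp_path_factory.mktemp("tps") / "p.tps"
    write_tps([("h1", config, [pts[:3]])], f)
    (sid, back, curves), = read_tps(f)
    assert sid == "h1" and back.p == config.p
    assert np.allclose(back.points, pts, atol=1e-6)
    assert np.allclose(curves[0], pts[:3], atol=1e-6)


def test_read_metadata_defaults_and_errors(tmp_path):
    f = tmp_path / "meta.csv"
    f.write_text("specimen_id,group\na,KLI\nb,KLI\nc,SHI\n")
    meta = read_metadata(f)
    assert len(meta) == 3
    assert set(meta["status"]) == {"unknown"}
    assert set(meta["element"]) == {"other"}

    dup = tmp_path / "dup.csv"
    dup.write_text("specimen_id,group\na,KLI\na,SHI\n")
    with pytest.raises(DatasetError, match="a"):
        read_metadata(dup)

    missing = tmp_path / "missing.csv"
    missing.write_text("specimen_id,period\na,PPNA\n")
    with pytest.raises(DatasetError, match="group"):
        read_metadata(missing)


def test_read_xyz_table(tmp_path):
    f = tmp_path / "spec1.csv"
    pd.DataFrame({"x": range(5), "y": range(5), "z": range(5)}).to_csv(f, index=False)
    sid, config = read_xyz_table(f)
    assert sid == "spec1" and config.p == 5 and config.dimension == 3

    g = tmp_path / "roles.csv"
    pd.DataFrame(
        {
            "x": range(5),
            "y": [0] * 5,
            "z": [1] * 5,
            "role": ["anatomical"] * 3 + ["semilandmark"] * 2,
        }
    ).to_csv(g, index=False)
    _, config = read_xyz_table(g)
    assert config.roles[3] == "semilandmark"

    small = tmp_path / "small.csv"
    pd.DataFrame({"x": [0, 1], "y": [0, 1], "z": [0, 1]}).to_csv(small, index=False)
    with pytest.raises(DatasetError):
        read_xyz_table(small)

    noz = tmp_path / "noz.csv"
    pd.DataFrame({"x": range(4), "y": range(4)}).to_csv(noz, index=False)
    with pytest.raises(DatasetError, match="z"):
        read_xyz_table(noz)


def _meta_frame(ids):
    return read_metadata_frame(ids)


def read_metadata_frame(ids):
    df = pd.DataFrame({"specimen_id": ids, "group": "KLI", "period": "", "status": "wild", "element": "M2"})
    return df.set_index("specimen_id", drop=False)


def test_assemble_dataset_joins_and_validates(unit_square):
    ids = ["a", "b", "c"]
    meta = read_metadata_frame(ids)
    ds = assemble_dataset([(i, unit_square) for i in ids], meta, "M2")
    assert len(ds) == 3 and ds.p == 4 and ds.k == 2
    assert ds.records[0].status == "wild"

    with pytest.raises(DatasetError, match="zzz"):
        assemble_dataset([("zzz", unit_square)], meta, "M2")

    bigger = LandmarkConfiguration(np.vstack([unit_square.points, [2.0, 2.0]]))
    with pytest.raises(DatasetError, match="b"):
        assemble_dataset([("a", unit_square), ("b", bigger)], meta, "M2")
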