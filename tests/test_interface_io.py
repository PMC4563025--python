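"""Table/config round trips, validation errors, and CLI smoke tests."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from pescale.cli import main
from pescale.io import (
    TrialTableError,
    load_config,
    read_table,
    read_trial_table,
    save_config,
    write_table,
)


def _mini_table():
    rows = []
    for pid in (1, 2):
        for t in (1, 2, 3):
            rows.append(
                {"participant_id": pid, "session": 1, "condition_id": "sd5_ev35",
                 "sd_level": "small", "sd_target": 5.0, "ev": 35.0,
                 "trial_in_condition": t, "reward": 30 + t, "prediction": 50 - t}
            )
    return pd.DataFrame(rows)


def test_write_read_round_trip(tmp_path):
    df = _mini_table()
    path = write_table(df, tmp_path / "trials.csv", {"seed": 1})
    back = read_trial_table(path)
    pd.testing.assert_frame_equal(back, df, check_dtype=False)
    # provenance header present
    assert open(path).readline().startswith("# config_hash=")


def test_duplicate_key_rejected(tmp_path):
    df = pd.concat([_mini_table(), _mini_table().iloc[[0]]], ignore_index=True)
    path = write_table(df, tmp_path / "dup.csv")
    with pytest.raises(TrialTableError, match="duplicated trial key"):
        read_trial_table(path)


def test_empty_and_missing_files(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(TrialTableError):
        read_trial_table(empty)
    with pytest.raises(FileNotFoundError):
        read_trial_table(tmp_path / "nope.csv")


def test_missing_column_and_bad_values(tmp_path):
    df = _mini_table().drop(columns=["reward"])
    path = write_table(df, tmp_path / "m.csv")
    with pytest.raises(TrialTableError, match="reward"):
        read_trial_table(path)
    df2 = _mini_table()
    df2["prediction"] = df2["prediction"].astype(object)
    df2.loc[0, "prediction"] = "oops"
    path2 = write_table(df2, tmp_path / "b.csv")
    with pytest.raises(TrialTableError, match="non-numeric"):
        read_trial_table(path2)


def test_non_contiguous_trials_rejected(tmp_path):
    df = _mini_table()
    df.loc[df.index[-1], "trial_in_condition"] = 9
    path = write_table(df, tmp_path / "g.csv")
    with pytest.raises(TrialTableError, match="non-contiguous"):
        read_trial_table(path)


def test_config_round_trip(tmp_path):
    cfg = {"seed": 3, "model": "aph-log", "mask": [2, 42]}
    for name in ("c.yaml", "c.json"):
        path = save_config(cfg, tmp_path / name)
        assert load_config(path) == cfg


def test_cli_simulate_fit_pipeline(tmp_path):
    runner = CliRunner()
    data = tmp_path / "cohort.csv"
    out = tmp_path / "fits.csv"
    r1 = runner.invoke(main, ["simulate-cohort", "--n", "1", "--seed", "1",
                              "--out", str(data)])
    assert r1.exit_code == 0, r1.output
    r2 = runner.invoke(main, ["fit", "--data", str(data), "--model", "rw",
                              "--starts", "2", "--out", str(out)])
    assert r2.exit_code == 0, r2.output
    fits = read_table(out)
    assert "alpha1" in fits.columns and len(fits) == 1
    assert 0 <= fits["alpha1"].iloc[0] <= 1


def test_cli_identical_invocations_identical_outputs(tmp_path):
    runner = CliRunner()
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    for path in (a, b):
        res = runner.invoke(main, ["simulate-task", "--seed", "5", "--out", str(path)])
        assert res.exit_code == 0, res.output
    assert a.read_bytes() == b.read_bytes()


def test_cli_missing_file_fails():
    runner = CliRunner()
    res = runner.invoke(main, ["fit", "--data", "does_not_exist.csv", "--out", "x.csv"])
    assert res.exit_code != 0


def test_cli_unknown_flag_fails():
    runner = CliRunner()
    res = runner.invoke(main, ["simulate-task", "--frobnicate"])
    assert res.exit_code != 0
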