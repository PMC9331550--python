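import numpy as np
import pandas as pd
import pytest

from svclogit.survey import (
    SchemaError,
    RawSurveyTable,
    apply_eligibility,
    decode_covariates,
    descriptive_table,
    encode_covariates,
    load_survey,
)


REGIONS = ("EC", "FS", "Gau", "KN", "Lim", "Mp", "NC", "NW", "WC")


def make_table(n=40, seed=0, missing=()):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "person_id": np.arange(n),
        "age": rng.integers(20, 85, n).astype(float),
        "sex": rng.choice(["Male", "Female"], n),
        "race": rng.choice(["African", "Colored", "Indian/Asian", "White"], n),
        "education": rng.choice(["No primary", "Primary", "Secondary", "Tertiary"], n),
        "marital": rng.choice(["Single", "Married", "Divorced/Separated/Widowed"], n),
        "wage_work": rng.choice(["Yes", "No"], n),
        "residence": rng.choice(["Urban", "Rural"], n),
        "region": rng.choice(list(REGIONS), n),
        "diabetes": rng.integers(0, 2, n).astype(float),
    })
    for col, idx in missing:
        df.loc[idx, col] = np.nan
    return RawSurveyTable(df=df)


class TestLoadSurvey:
    def test_wellformed_csv(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("person_id,age,region,sex,diabetes\n1,40,EC,Male,0\n"
                     "2,55,WC,Female,1\n3,35,Gau,Male,0\n")
        t = load_survey(p)
        assert t.n == 3
        assert t.df["age"].tolist() == [40.0, 55.0, 35.0]

    def test_unparseable_age_becomes_missing_row_kept(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("age,region,diabetes\nabc,EC,0\n50,WC,1\n")
        t = load_survey(p)
        assert t.n == 2
        assert np.isnan(t.df["age"].iloc[0])

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("age,diabetes\n40,0\n")
        with pytest.raises(SchemaError, match="region"):
            load_survey(p)

    def test_schema_rename_and_tsv(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("Alder\tProv\tdiab\n40\tEC\t1\n")
        t = load_survey(p, schema={"age": "Alder", "region": "Prov",
                                   "diabetes": "diab"})
        assert t.df["region"].iloc[0] == "EC"

    def test_write_read_roundtrip(self, tmp_path):
        t = make_table(20)
        p = tmp_path / "r.csv"
        t.df.to_csv(p, index=False)
        back = load_survey(p)
        pd.testing.assert_frame_equal(
            back.df[t.df.columns].astype(t.df.dtypes), t.df)


class TestEligibility:
    COVS = ("sex", "race")

    def test_age_35_boundary_inclusive(self):
        t = make_table(3)
        t.df["age"] = [34.0, 35.0, 60.0]
        out = apply_eligibility(t, "diabetes", self.COVS)
        assert out.n == 2
        assert out.df["age"].min() == 35.0

    def test_missing_outcome_dropped(self):
        t = make_table(5)
        t.df["age"] = 50.0
        t.df.loc[2, "diabetes"] = np.nan
        out = apply_eligibility(t, "diabetes", self.COVS)
        assert out.n == 4

    def test_listwise_deletion_matches_row_scan(self):
        t = make_table(200, seed=5, missing=[
            ("sex", [3, 10]), ("race", [10, 50, 60]), ("diabetes", [7])])
        out = apply_eligibility(t, "diabetes", self.COVS)
        df = t.df
        expect = ((df["age"] >= 35) & df["diabetes"].notna()
                  & df["sex"].notna() & df["race"].notna()).sum()
        assert out.n == expect

    def test_idempotent(self):
        t = make_table(100, seed=2)
        once = apply_eligibility(t, "diabetes", self.COVS)
        twice = apply_eligibility(once, "diabetes", self.COVS)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_empty_result_raises(self):
        t = make_table(4)
        t.df["age"] = 20.0
        with pytest.raises(ValueError, match="no rows remain"):
            apply_eligibility(t, "diabetes", self.COVS)


class TestEncodeCovariates:
    def test_reference_levels_omitted(self):
        t = make_table(60)
        t.df["age"] = 50.0
        ds = encode_covariates(t, REGIONS, "diabetes", covariates=("race",))
        assert list(ds.X.columns) == [
            "race=Colored", "race=Indian/Asian", "race=White"]

    def test_all_reference_row_is_zero(self):
        t = make_table(40)
        t.df.loc[0, ["sex", "race", "age"]] = ["Male", "African", 40.0]
        ds = encode_covariates(t, REGIONS, "diabetes", covariates=("sex", "race"))
        assert ds.X.iloc[0].sum() == 0.0

    def test_row_sums_per_variable_at_most_one(self):
        t = make_table(300, seed=9)
        ds = encode_covariates(t, REGIONS, "diabetes",
                               covariates=("sex", "race", "education"))
        for var in ("sex", "race", "education"):
            block = [c for c in ds.X.columns if c.startswith(f"{var}=")]
            assert set(ds.X[block].sum(axis=1).unique()) <= {0.0, 1.0}

    def test_decode_roundtrip(self):
        t = make_table(150, seed=3)
        covs = ("sex", "race", "education", "marital")
        ds = encode_covariates(t, REGIONS, "diabetes", covariates=covs)
        back = decode_covariates(ds)
        for var in covs:
            assert (back[var].to_numpy() == t.df[var].to_numpy()).all()

    def test_unseen_level_rejected(self):
        t = make_table(10)
        t.df.loc[0, "sex"] = "Other"
        with pytest.raises(ValueError, match="Other"):
            encode_covariates(t, REGIONS, "diabetes", covariates=("sex",))

    def test_age_bins_integer_years(self):
        t = make_table(50, seed=1)
        t.df["age"] = np.linspace(35, 80, 50).round()
        ds = encode_covariates(t, REGIONS, "diabetes", covariates=("sex",))
        assert ds.bin_grid[0] == 35.0
        assert np.all(ds.bin_grid[ds.age_bin] == np.floor(ds.age))


class TestDescriptiveTable:
    def test_survey_scale_percentages(self):
        # the full-sample shares: 33,151 males of 68,986 -> 48.1%;
        # 15,455 Gauteng residents -> 22.4%
        df = pd.DataFrame({
            "sex": ["Male"] * 33151 + ["Female"] * 35835,
            "region": ["Gau"] * 15455 + ["other"] * (68986 - 15455),
        })
        tab = descriptive_table(df, ["sex", "region"])
        get = lambda v, l: tab.query("variable == @v and level == @l")["percent"].iloc[0]
        assert get("sex", "Male") == 48.1
        assert get("sex", "Female") == 51.9
        assert get("region", "Gau") == 22.4

    def test_single_level_is_100(self):
        df = pd.DataFrame({"sex": ["Male"] * 7})
        tab = descriptive_table(df, ["sex"])
        assert tab["percent"].iloc[0] == 100.0

    def test_counts_sum_to_n_and_percents_to_100(self):
        t = make_table(500, seed=11)
        tab = descriptive_table(t)
        for _, grp in tab.groupby("variable"):
            assert grp["count"].sum() == 500
            assert grp["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_half_up_rounding(self):
        # 5/8 = 62.5% exactly; 3/8 = 37.5% -> both keep the .5 (1 decimal)
        df = pd.DataFrame({"sex": ["Male"] * 5 + ["Female"] * 3})
        tab = descriptive_table(df, ["sex"])
        assert sorted(tab["percent"]) == [37.5, 62.5]
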