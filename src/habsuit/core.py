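"""Shared vocabulary: environmental factors, seasons, column names."""

FACTORS = ("temp", "sal", "depth")
SEASONS = ("spring", "summer", "autumn", "winter")

#: env-table column holding each factor's value
FACTOR_COLUMNS = {"temp": "temp_c", "sal": "sal_psu", "depth": "depth_m"}

CATCH_COLUMNS = ["station_id", "lat", "lon", "season", "species", "weight_g", "tow_h"]
ENV_COLUMNS = ["station_id", "lat", "lon", "season", "temp_c", "sal_psu", "depth_m", "source"]
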