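# Default analysis regions: editable lat-lon boxes on the synthetic grid.
# These loosely stand in for four fire-prone regions and are meant to exercise
# the regional-summary code path, not to reproduce any real-world polygon.
region,lat_min,lat_max,lon_min,lon_max
australia,-40,-12,112,154
sub_saharan_africa,-12,12,8,42
siberia,48,68,78,132
canada,48,64,-122,-88
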