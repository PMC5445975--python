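# Generated by deldesign.fixtures.write_fixture_files(seed=42); regenerated and
# verified against the generator in tests/test_fixtures.py.
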