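{
 "conchifera.nwk": "46db4649e7b533ff89abe96220e1e7760df4cd4020ce22dfe25771f938a29810",
 "coreset_proteins_setting2.json": "5837ca5920c0cf81915df36ec2b70c4d275e2a4aa2cbb3b444699bebf9180a5b",
 "domain_profiles_synthetic.json": "1ca05142f508936c3d78502c22a3e9649e73ca92378c55e24175d63da0aa5a2d",
 "shared_domains.json": "398860a0ffef013b74c53ff5008ddbea6f413b49449e5048b4fbf798739effe4",
 "table1.tsv": "e8cc4ef22a4b779aa53d69e8512e8bca22056bae870ba8cf9a4ef0b06b3564af"
}
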