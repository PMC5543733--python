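{
  "chou_fasman.tsv": "ee81c430aff25cb25fb5a803d8af99955830974801b31a157a977f425c825fe6",
  "emini_surface.tsv": "83aa63135de007eda5c09e9b18774511e6cdce8be9859caffe54c2b1dc52852e",
  "flexibility.tsv": "16f3ebb8016fa5f5e8dba7b94bcb01289b1ee481fd4ba57bcaec43c622f91e0d",
  "gor_info_synthetic.tsv": "0a8e7830f88f77123afe536b913692cee703742fe0042888a63cd2eef409b9ba",
  "hopp_woods.tsv": "69a31d78069fdda27317d2f17ad1aedd6cabd679e64ec89e4b5e8a04eaa181d4",
  "kyte_doolittle.tsv": "b7d6966378a3ed1eb1d41b5f03904b2d664d822a9eebc35cbfbfa539076989ad"
}
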