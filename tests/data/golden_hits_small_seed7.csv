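organism,resistance_gene_id,resistance_scaffold,resistance_start,resistance_stop,resistance_evalue,resistance_pct_identity,sm_gene_id,sm_scaffold,sm_start,sm_stop,center_distance,end_gap
org0003,g000007,scaf03,255954,263360,6.75857044116799e-173,65.4,g000008,scaf03,309172,311544,50701,45811
org0003,g000005,scaf02,314329,320024,2.2083636064170943e-108,56.9,g000006,scaf02,343723,348334,28852,23698
org0008,g000003,scaf01,329408,331994,7.518892236094828e-93,39.3,g000004,scaf01,388042,393008,59824,56047
org0009,g000001,scaf03,62497,66446,5.217029019540972e-137,44.1,g000002,scaf03,74678,76375,11055,8231
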