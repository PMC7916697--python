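id,logp,sas,qed,role
NNC 55-0365,6.8147,3.678636,0.273518,reference
NNC 55-0396,6.0345,3.716436,0.351695,reference
NNC 55-0397,6.2805,3.718535,0.337773,reference
Mibefradil,5.2709,3.71918,0.367183,reference
TC 1,6.1671,4.433975,0.402836,candidate
TC 2,5.3351,5.24865,0.408449,candidate
TC 3,4.8963,4.777741,0.474028,candidate
TC 4,5.0404,4.731275,0.441386,candidate
TC 5,5.5879,4.951457,0.415026,candidate
TC 6,4.4585,4.79633,0.469604,candidate
TC 7,3.6902,4.806084,0.63381,candidate
TC 8,6.2697,4.851381,0.242332,candidate
TC 10,4.1891,4.542497,0.312353,candidate
TC 11,5.372,3.089346,0.276759,candidate
TC 12,4.9472,3.971406,0.248549,candidate
TC 13,5.7028,4.449589,0.406663,candidate
TC 15,4.73,3.921747,0.368816,candidate
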