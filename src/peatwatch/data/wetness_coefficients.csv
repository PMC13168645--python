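sensor_id,blue,green,red,nir,swir1,swir2,K1,K2,lambda_m,version
TM,0.0315,0.2021,0.3102,0.1594,-0.6806,-0.6109,607.76,1260.56,1.145e-05,1
ETM+,0.2626,0.2141,0.0926,0.0656,-0.7629,-0.5388,666.09,1282.71,1.145e-05,1
OLI,0.1511,0.1973,0.3283,0.3407,-0.7117,-0.4559,774.8853,1321.0789,1.0895e-05,1
SYNTHETIC,0.0315,0.2021,0.3102,0.1594,-0.6806,-0.6109,607.76,1260.56,1.145e-05,1
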