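treatment,fgp_mean,fgp_sd,mgt_mean,mgt_sd,mgr_mean,mgr_sd,fdg_mean,fdg_sd,ldg_mean,ldg_sd,cvt_mean,cvt_sd,cvg_mean,cvg_sd,gri_mean,gri_sd,gi_mean,gi_sd,t50_mean,t50_sd
GA3_paper_10C,17,2.4,30.3,2.4,0.033,0.004,26,3.1,39,5.2,14.9,2.3,3.3,0.41,0.50,0.07,92,12.3,28.3,2.9
GA3_paper_15C,14,1.6,36,4.1,0.028,0.003,32,2.7,40,3.5,15.7,1.9,2.8,0.31,0.28,0.03,50,4.3,32,2.6
GA3_agar_10C,32,2.5,32.5,3.5,0.031,0.02,25,2.1,37,3.0,15.8,1.4,3.1,0.23,0.94,0.07,171,13.2,32,2.4
GA3_agar_15C,23,1.9,34.4,2.9,0.029,0.002,29,2.2,42,3.3,10.4,1.2,2.9,0.23,0.73,0.06,133,10.6,33.5,2.8
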