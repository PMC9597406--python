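participant,pre_transition_grade,cmet_crouch,cmet_pre,ca2_crouch,ca2_pre,ccp_a2,camax_crouch,camax_pre,ccp_amax,cavol_crouch,cavol_pre,ccp_avol
1,12,172.5,189.5,566.0,290.8,Y,292.2,196.8,Y,167.1,125.7,Y
2,18,226.4,236.3,1382.3,794.3,Y,575.9,399.7,Y,308.1,236.9,Y
3,18,229.9,266.9,1410.1,799.4,Y,533.8,463.1,Y,222.5,161.4,Y
4,12,137.6,182.5,605.2,373.1,Y,429.4,227.2,Y,169.5,155.9,Y
5,18,170.9,200.6,,,,,,,,,
6,12,204.9,202.5,1409.4,454.2,N,747.6,368.4,N,239.7,154.4,N
7,18,174.6,245.6,,,,,,,,,
8,18,137.6,199.3,284.4,211.4,Y,219.5,165.6,Y,166.9,143.4,Y
9,18,169.6,215.9,584.3,308.0,Y,380.7,249.3,Y,198.8,156.8,Y
10,18,160.1,217.0,469.2,359.1,Y,297.3,233.9,Y,167.2,154.2,Y
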