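{"signature":[1,2,2,1],"reduced":[["m",0],["m",1],["m",2],["m",3],["u1",4],["u2",4],["m",5],["m",6],["m",7]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[1,1,[3]],[-1,1,[6]],[-2,1,[0,4]],[-1,1,[0,5]]],[[1,1,[1]],[1,1,[7]],[-1,1,[8]],[-1,1,[1,4]],[-2,1,[1,5]]],[[1,1,[2]],[3,1,[1,3]],[-3,1,[1,6]],[-2,1,[2,4]],[-1,1,[2,5]]],[[1,1,[0,1]],[1,1,[1,3]],[-1,1,[1,6]],[-2,3,[2,4]],[-1,3,[2,5]]],[[1,1,[0,7]],[-1,1,[0,8]],[-1,1,[1,3]],[1,1,[1,6]],[1,3,[2,4]],[-1,3,[2,5]]],[[1,1,[2]],[3,1,[0,7]],[-3,1,[0,8]],[-1,1,[2,4]],[-2,1,[2,5]]],[[1,1,[0,1]],[1,1,[0,7]],[-1,1,[0,8]],[-1,3,[2,4]],[-2,3,[2,5]]]],"checksum":"57594b06fceed9ca25933ff36f6adb37c3331eea857255b5b582e253a624439b"}
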